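"""Type-II ROC analysis of confidence ratings.

The type-II ROC conditions on response *correctness* rather than on
the stimulus: sweeping a criterion k over the confidence scale, a
"type-II hit" is a rating >= k on a correct trial and a "type-II
false alarm" is a rating >= k on an incorrect trial.  The area under
the resulting curve (AROC) measures metacognitive ability - how well
confidence tracks accuracy - without assuming any distribution for
the ratings.  Chance corresponds to an AROC of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["AROCResult", "DegenerateCellError", "type2_aroc", "aroc_by_cell"]


class DegenerateCellError(ValueError):
    """All trials correct or all incorrect: the type-II ROC is undefined.

    Callers should treat the cell as missing rather than impute a
    value (imputing 0.5 would bias group analyses toward chance).
    """


@dataclass
class AROCResult:
    aroc: float
    curve_points: np.ndarray  # (k, 2): (type-II FA rate, type-II hit rate)
    n_correct: int
    n_incorrect: int


def type2_aroc(
    correct: Sequence,
    confidence: Sequence,
    scale_max: int = 5,
) -> AROCResult:
    """Area under the type-II ROC for (correct, confidence) pairs.

    For every criterion k in 2..``scale_max`` the hit rate
    P(confidence >= k | correct) is plotted against the false-alarm
    rate P(confidence >= k | incorrect); with the (0, 0) and (1, 1)
    endpoints added, the area is taken by the trapezoid rule.  Ties at
    a criterion therefore receive half credit, which makes the area
    identical to the rank-sum (Mann-Whitney) probability that a random
    correct trial carries higher confidence than a random incorrect
    one.
    """
    correct = np.asarray(correct, dtype=bool)
    conf = np.asarray(confidence)
    if correct.shape != conf.shape:
        raise ValueError("correct and confidence must have equal length")
    if correct.size == 0:
        raise ValueError("empty input")
    if np.any((conf < 1) | (conf > scale_max)):
        raise ValueError(f"confidence ratings must lie in 1..{scale_max}")

    n_c = int(correct.sum())
    n_i = int((~correct).sum())
    if n_c == 0 or n_i == 0:
        raise DegenerateCellError(
            "type-II AROC undefined without both correct and incorrect trials"
        )

    crit = np.arange(2, scale_max + 1)
    hits = np.array([(conf[correct] >= k).mean() for k in crit])
    fas = np.array([(conf[~correct] >= k).mean() for k in crit])
    pts = np.column_stack([fas, hits])
    pts = np.vstack([[0.0, 0.0], pts, [1.0, 1.0]])
    # Criteria sweep high->low traces the curve from (0,0) to (1,1);
    # sort by FA rate (hit rate ties broken by hit rate) for the trapezoid.
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    area = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return AROCResult(aroc=area, curve_points=pts, n_correct=n_c, n_incorrect=n_i)


def aroc_by_cell(
    records: pd.DataFrame,
    factors: Sequence[str],
    correct_col: str = "correct",
    confidence_col: str = "confidence",
    scale_max: int = 5,
) -> pd.DataFrame:
    """Type-II AROC per cell of a grouping (participant x condition x ...).

    Degenerate cells - no incorrect trials or no correct trials - get
    a missing AROC (NaN) so that downstream repeated-measures stages
    can apply their own deletion policy instead of receiving an
    imputed chance value.
    """
    factors = list(factors)
    if not factors:
        raise ValueError("at least one grouping factor is required")
    rows = []
    for keys, sub in records.groupby(factors, sort=True, observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(factors, keys))
        try:
            res = type2_aroc(sub[correct_col], sub[confidence_col], scale_max)
            row.update(
                aroc=res.aroc, n_correct=res.n_correct, n_incorrect=res.n_incorrect
            )
        except DegenerateCellError:
            row.update(
                aroc=np.nan,
                n_correct=int(sub[correct_col].sum()),
                n_incorrect=int((~sub[correct_col].astype(bool)).sum()),
            )
        rows.append(row)
    if not rows:
        raise ValueError("empty grouping")
    return pd.DataFrame(rows)
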
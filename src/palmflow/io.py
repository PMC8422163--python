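"""Trial-table input/output.

The on-disk format is a plain delimited text file (CSV), one row per
trial, long format.  ``TRIAL_SCHEMA`` documents the canonical column
set; external deposits with different headers can be adapted with a
``column_map`` (external name -> canonical name), supplied directly
or inside a config mapping under the key ``"column_map"``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

__all__ = ["TRIAL_SCHEMA", "read_trials", "write_trials"]

SCHEMA_VERSION = "1"

#: Canonical trial-table columns and their meaning.
TRIAL_SCHEMA = {
    "participant": "integer participant id",
    "session": "testing session (1 or 2)",
    "block": "0-based block ordinal within participant",
    "condition": "motion axis: vertical | horizontal | oblique",
    "duration_ms": "stimulus duration in milliseconds",
    "duration_level": "0-based index on the duration grid",
    "correct_interval": "interval containing the target direction (1 or 2)",
    "trial_in_condition": "0-based trial ordinal within condition",
    "is_training": "True for feedback training trials",
    "is_topup": "True for crash-replacement trials",
    "response_interval": "interval chosen by the participant (1 or 2)",
    "correct": "response_interval == correct_interval",
    "confidence": "confidence rating 1-5 (empty on training trials)",
    "hand_temp_c": "hand temperature before the block, deg C",
    "body_temp_c": "body temperature before the block, deg C",
    "age_years": "participant age",
    "palm_size_cm": "hand size minus finger size, cm",
    "hand_size_cm": "hand size, cm",
    "finger_size_cm": "finger size, cm",
    "condition_order": "participant's condition order, e.g. vertical-oblique-horizontal",
}

REQUIRED = ("participant", "condition", "correct_interval", "response_interval", "correct")


def write_trials(records: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a trial table as CSV (lossless round-trip with read_trials)."""
    records.to_csv(path, index=False)


def read_trials(
    path: Union[str, Path],
    column_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Read a trial table, optionally renaming external columns.

    ``column_map`` maps the file's column names to the canonical
    names in :data:`TRIAL_SCHEMA`.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing required columns: {missing}")
    if "correct" in df.columns:
        df["correct"] = df["correct"].astype(bool)
    for flag in ("is_training", "is_topup"):
        if flag in df.columns:
            df[flag] = df[flag].astype(bool)
    return df
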
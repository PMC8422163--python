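"""Full analysis orchestration for the tactile oblique-effect study.

Stages: participant exclusions, performance/confidence/AROC
aggregation, within-subject error bars, the oblique-effect Bayes
battery (chance tests, 3 x 10 repeated-measures ANOVAs, condition and
duration post-hocs, sequential recruitment curve), and the
individual-difference / task-effect correlation batteries.  A report
bundle (JSON plus figures) mirrors the content of the study's main
figures.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import bayes
from .metacognition import aroc_by_cell

__all__ = [
    "apply_exclusions",
    "summarize_performance",
    "within_subject_errorbars",
    "participant_summaries",
    "run_oblique_battery",
    "run_difference_batteries",
    "render_report",
    "BatteryResult",
]

CONDITIONS = ("vertical", "horizontal", "oblique")
MEASURES = ("accuracy", "confidence", "aroc")
#: "combined" pools all trials regardless of condition (trial-weighted).
CONDITION_SETS = ("combined",) + CONDITIONS


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------

def apply_exclusions(
    records: pd.DataFrame,
    modal_share_threshold: float = 0.90,
    drop_training: bool = True,
) -> tuple:
    """Drop pathological participants and training trials.

    A participant is excluded when their modal response key accounts
    for more than ``modal_share_threshold`` of experimental trials
    (responding "almost exclusively with one response key").  Returns
    the filtered records and a log of exclusions with reasons.
    """
    df = records.copy()
    log: list[dict] = []
    if drop_training and "is_training" in df.columns:
        n_train = int(df["is_training"].sum())
        if n_train:
            log.append({"action": "drop-training-trials", "n_trials": n_train})
        df = df[~df["is_training"]]
    for pid, sub in df.groupby("participant"):
        share = sub["response_interval"].value_counts(normalize=True).iloc[0]
        if share > modal_share_threshold:
            log.append(
                {
                    "action": "exclude-participant",
                    "participant": int(pid),
                    "reason": "single-key responding",
                    "modal_response_share": float(share),
                }
            )
    excluded = {e["participant"] for e in log if e["action"] == "exclude-participant"}
    df = df[~df["participant"].isin(excluded)].reset_index(drop=True)
    return df, log


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _with_combined(records: pd.DataFrame) -> pd.DataFrame:
    pooled = records.copy()
    pooled["condition"] = "combined"
    return pd.concat([records, pooled], ignore_index=True)


def summarize_performance(records: pd.DataFrame) -> dict:
    """Percent-correct tables.

    Returns ``by_condition`` (participant x condition incl. the
    trial-weighted "combined" pool), ``by_condition_duration``, and
    ``group`` (group means per condition set), all in percent.
    """
    if records.empty:
        raise ValueError("no trials to summarize")
    aug = _with_combined(records)
    by_cond = (
        aug.groupby(["participant", "condition"], observed=True)["correct"]
        .mean()
        .mul(100.0)
        .rename("accuracy_pct")
        .reset_index()
    )
    for cond in CONDITIONS:
        if cond not in set(records["condition"]):
            raise ValueError(f"condition {cond!r} has no trials")
    by_cond_dur = (
        aug.groupby(["participant", "condition", "duration_level"], observed=True)[
            "correct"
        ]
        .mean()
        .mul(100.0)
        .rename("accuracy_pct")
        .reset_index()
    )
    group = (
        by_cond.groupby("condition", observed=True)["accuracy_pct"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return {
        "by_condition": by_cond,
        "by_condition_duration": by_cond_dur,
        "group": group,
    }


def measure_cells(
    records: pd.DataFrame,
    measure: str,
    by: Sequence[str] = ("participant", "condition", "duration_level"),
    include_combined: bool = False,
) -> pd.DataFrame:
    """Per-cell values of one outcome measure, long format (column 'value').

    accuracy is percent correct; confidence the mean rating; aroc the
    type-II AROC (NaN on degenerate cells).
    """
    df = _with_combined(records) if include_combined else records
    by = list(by)
    if measure == "accuracy":
        out = (
            df.groupby(by, observed=True)["correct"].mean().mul(100.0).rename("value").reset_index()
        )
    elif measure == "confidence":
        out = df.groupby(by, observed=True)["confidence"].mean().rename("value").reset_index()
    elif measure == "aroc":
        out = aroc_by_cell(df, by).rename(columns={"aroc": "value"})[by + ["value"]]
    else:
        raise ValueError(f"unknown measure {measure!r}")
    return out


def within_subject_errorbars(cell_means: pd.DataFrame) -> pd.DataFrame:
    """Within-subject standard errors for a participant x condition table.

    Subject-centred (Cousineau) normalization - each participant's
    mean is removed and the grand mean restored - with the Morey
    small-k bias correction ``sqrt(k / (k - 1))`` applied to the
    per-condition standard errors.  ``cell_means`` is long format with
    columns participant, condition, value.
    """
    wide = cell_means.pivot(index="participant", columns="condition", values="value")
    if wide.isna().any().any():
        raise ValueError("within-subject error bars need a complete table")
    n, k = wide.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    if k < 2:
        raise ValueError("need at least 2 conditions")
    normalized = wide.sub(wide.mean(axis=1), axis=0) + wide.to_numpy().mean()
    corr = math.sqrt(k / (k - 1))
    se = normalized.std(ddof=1) / math.sqrt(n) * corr
    return pd.DataFrame(
        {
            "condition": wide.columns,
            "mean": wide.mean().to_numpy(),
            "within_subject_se": se.to_numpy(),
        }
    )


def participant_summaries(records: pd.DataFrame) -> dict:
    """Per-participant measures at condition and block granularity.

    ``by_condition``: participant x condition-set (combined + 3) x
    measure.  ``by_block``: the same measures per experimental block,
    with the block's hand temperature, hand-minus-body temperature
    and block ordinal, for the within-subject battery.
    ``covariates``: age, palm size and condition order per participant.
    """
    aug = _with_combined(records)
    acc = (
        aug.groupby(["participant", "condition"], observed=True)["correct"]
        .mean()
        .mul(100.0)
        .rename("accuracy")
    )
    conf = (
        aug.groupby(["participant", "condition"], observed=True)["confidence"]
        .mean()
        .rename("confidence")
    )
    aroc = (
        aroc_by_cell(aug, ["participant", "condition"])
        .set_index(["participant", "condition"])["aroc"]
    )
    by_condition = pd.concat([acc, conf, aroc], axis=1).reset_index()

    # Block number within condition set: pooled trials keep their own block
    # ordinal; per-condition rows use the 0-based block rank in that condition.
    aug = aug.copy()
    aug["block_rank"] = aug.groupby(["participant", "condition"], observed=True)[
        "block"
    ].transform(lambda b: b.rank(method="dense").astype(int) - 1)
    gb = aug.groupby(["participant", "condition", "block_rank"], observed=True)
    blk = gb.agg(
        accuracy=("correct", lambda c: 100.0 * c.mean()),
        confidence=("confidence", "mean"),
        hand_temp_c=("hand_temp_c", "mean"),
        body_temp_c=("body_temp_c", "mean"),
    ).reset_index()
    blk_aroc = aroc_by_cell(aug, ["participant", "condition", "block_rank"])
    blk = blk.merge(
        blk_aroc[["participant", "condition", "block_rank", "aroc"]],
        on=["participant", "condition", "block_rank"],
        how="left",
    )
    blk["hand_minus_body_temp_c"] = blk["hand_temp_c"] - blk["body_temp_c"]

    cov_cols = [
        c
        for c in ("age_years", "palm_size_cm", "condition_order")
        if c in records.columns
    ]
    covariates = (
        records.groupby("participant")[cov_cols].first().reset_index()
        if cov_cols
        else pd.DataFrame({"participant": sorted(records["participant"].unique())})
    )
    return {"by_condition": by_condition, "by_block": blk, "covariates": covariates}


# ---------------------------------------------------------------------------
# Oblique-effect battery
# ---------------------------------------------------------------------------

def run_oblique_battery(
    records: pd.DataFrame,
    seed: Optional[int] = None,
    mc_iterations: int = bayes.DEFAULT_MC_ITERATIONS,
    sequential: bool = True,
    sequential_mc_iterations: Optional[int] = None,
    n_min: int = 12,
    bf_threshold: float = 6.0,
) -> dict:
    """The study's primary test battery on a post-exclusion trial table.

    * one-sided one-sample Bayes-factor t-tests against chance for
      accuracy (50%) and AROC (0.5), per condition and combined;
    * three 3 x 10 repeated-measures ANOVAs (condition x duration) on
      accuracy, confidence and AROC, reported as inclusion Bayes
      factors with verdict bands;
    * post-hoc paired Bayes factors between conditions for each
      measure, and between all duration pairs for confidence (the
      half-matrix of 45 unordered pairs for 10 levels);
    * the sequential Bayes-factor recruitment curve for the condition
      effect on accuracy.
    """
    ss = np.random.SeedSequence(0 if seed is None else seed)
    seeds = ss.spawn(8)

    summaries = participant_summaries(records)
    by_cond = summaries["by_condition"]

    chance_tests = {}
    for measure, null, label in (("accuracy", 50.0, "%"), ("aroc", 0.5, "")):
        for cond in CONDITION_SETS:
            vals = by_cond.loc[by_cond["condition"] == cond, measure].dropna()
            chance_tests[f"{measure}:{cond}"] = bayes.bf_one_sample_t(
                vals, null, sided="greater", effect=f"{measure} {cond} > {null}{label}"
            )

    anovas: dict = {}
    for i, measure in enumerate(MEASURES):
        cells = measure_cells(records, measure)
        cells = cells.rename(columns={"duration_level": "duration"})
        anovas[measure] = bayes.bf_rm_anova(
            cells,
            factors=("condition", "duration"),
            mc_iterations=mc_iterations,
            seed=seeds[i],
        )

    condition_posthocs: dict = {}
    for measure in MEASURES:
        wide = by_cond[by_cond["condition"] != "combined"].pivot(
            index="participant", columns="condition", values=measure
        )[list(CONDITIONS)]
        condition_posthocs[measure] = bayes.bf_posthoc_pairs(wide.dropna())

    conf_cells = measure_cells(records, "confidence")
    conf_wide = conf_cells.pivot_table(
        index="participant", columns="duration_level", values="value"
    )
    duration_pairs = bayes.bf_posthoc_pairs(conf_wide.dropna())
    n_levels = conf_wide.shape[1]
    half = np.full((n_levels, n_levels), np.nan)
    for res in duration_pairs:
        a, b = res.effect.split(" vs ")
        i, j = int(a), int(b)
        half[max(i, j), min(i, j)] = res.bf10
    duration_posthoc_matrix = pd.DataFrame(
        half, index=conf_wide.columns, columns=conf_wide.columns
    )

    seq = None
    if sequential:
        acc_cond = measure_cells(records, "accuracy", by=("participant", "condition"))
        seq = bayes.sequential_bf(
            acc_cond,
            effect="condition",
            factors=("condition",),
            threshold=bf_threshold,
            n_min=n_min,
            mc_iterations=(
                sequential_mc_iterations
                if sequential_mc_iterations is not None
                else mc_iterations
            ),
            seed=int(seeds[7].generate_state(1)[0] % (2**31)),
        )

    return {
        "chance_tests": chance_tests,
        "rm_anovas": anovas,
        "condition_posthocs": condition_posthocs,
        "duration_posthocs_confidence": duration_pairs,
        "duration_posthoc_matrix": duration_posthoc_matrix,
        "sequential": seq,
        "summaries": summaries,
        "verdict_table": {
            measure: anovas[measure].verdicts() for measure in MEASURES
        },
    }


# ---------------------------------------------------------------------------
# Individual-difference / task-effect batteries
# ---------------------------------------------------------------------------

@dataclass
class BatteryResult:
    """Correlation/ANOVA batteries over covariates.

    ``between_subject``: 2 covariates x 3 measures x 4 condition sets
    = 24 correlations with Bayes factors.  ``order_anovas``: 12
    condition-order ANOVAs (3 measures x 4 condition sets).
    ``within_subject``: per participant, 3 block covariates x 3
    measures x 4 condition sets = 36 correlation coefficients, and
    ``within_subject_group``: the group-level one-sample Bayes-factor
    t-tests on each coefficient's distribution.
    """

    between_subject: pd.DataFrame
    order_anovas: pd.DataFrame
    within_subject: pd.DataFrame
    within_subject_group: pd.DataFrame


BETWEEN_VARS = ("age_years", "palm_size_cm")
WITHIN_VARS = ("hand_temp_c", "hand_minus_body_temp_c", "block_rank")


def run_difference_batteries(
    summaries: dict,
    mc_iterations: int = bayes.DEFAULT_MC_ITERATIONS,
    seed: Optional[int] = None,
) -> BatteryResult:
    """Between- and within-subject covariate batteries on participant summaries."""
    by_cond = summaries["by_condition"]
    by_block = summaries["by_block"]
    cov = summaries["covariates"]
    merged = by_cond.merge(cov, on="participant")

    rows = []
    for var, measure, cond in itertools.product(BETWEEN_VARS, MEASURES, CONDITION_SETS):
        sub = merged[merged["condition"] == cond][[var, measure]].dropna()
        row = {"variable": var, "measure": measure, "condition": cond}
        try:
            res = bayes.bf_correlation(sub[var], sub[measure])
            row.update(
                r=res.extra["r"], r2=res.extra["r2"], bf10=res.bf10, bf01=res.bf01,
                n=res.extra["n"],
            )
        except ValueError as e:
            row.update(r=np.nan, r2=np.nan, bf10=np.nan, bf01=np.nan, n=len(sub),
                       note=str(e))
        rows.append(row)
    between = pd.DataFrame(rows)

    ss = np.random.SeedSequence(0 if seed is None else seed)
    order_seeds = iter(ss.spawn(len(MEASURES) * len(CONDITION_SETS)))
    rows = []
    if "condition_order" in cov.columns:
        for measure, cond in itertools.product(MEASURES, CONDITION_SETS):
            sub = merged[merged["condition"] == cond][
                ["condition_order", measure]
            ].dropna()
            res = bayes.bf_between_anova(
                sub[measure],
                sub["condition_order"],
                mc_iterations=mc_iterations,
                seed=next(order_seeds),
                effect=f"order on {measure} ({cond})",
            )
            rows.append(
                {
                    "measure": measure,
                    "condition": cond,
                    "bf10": res.bf10,
                    "bf01": res.bf01,
                    "mc_error": res.mc_error,
                }
            )
    order_anovas = pd.DataFrame(rows)

    rows = []
    for pid, sub in by_block.groupby("participant"):
        for var, measure, cond in itertools.product(
            WITHIN_VARS, MEASURES, CONDITION_SETS
        ):
            cells = sub[sub["condition"] == cond][[var, measure]].dropna()
            row = {
                "participant": pid,
                "variable": var,
                "measure": measure,
                "condition": cond,
            }
            try:
                r = float(np.corrcoef(cells[var], cells[measure])[0, 1])
            except Exception:
                r = np.nan
            if cells.shape[0] < 3 or cells[var].std() == 0 or cells[measure].std() == 0:
                r = np.nan
            row.update(r=r, r2=(r * r if np.isfinite(r) else np.nan), n=len(cells))
            rows.append(row)
    within = pd.DataFrame(rows)

    rows = []
    for (var, measure, cond), sub in within.groupby(
        ["variable", "measure", "condition"], sort=True
    ):
        coefs = sub["r"].dropna()
        row = {"variable": var, "measure": measure, "condition": cond, "n": len(coefs)}
        try:
            res = bayes.bf_one_sample_t(coefs, 0.0, sided="two")
            row.update(bf10=res.bf10, bf01=res.bf01, mean_r=float(coefs.mean()),
                       median_r2=float((coefs**2).median()))
        except ValueError as e:
            row.update(bf10=np.nan, bf01=np.nan, mean_r=np.nan, median_r2=np.nan,
                       note=str(e))
        rows.append(row)
    within_group = pd.DataFrame(rows)

    return BatteryResult(
        between_subject=between,
        order_anovas=order_anovas,
        within_subject=within,
        within_subject_group=within_group,
    )


from .report import render_report  # noqa: E402  (re-export: the renderer builds on this module)
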
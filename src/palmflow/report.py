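"""Report bundle: structured JSON summary plus figure analogues.

Figures mirror the study's main displays: per-participant accuracy
distributions with chance tests, the sequential Bayes-factor
recruitment curve, condition means with within-subject error bars,
the duration-pair Bayes-factor heat map for confidence, and violin
plots of the covariate-battery BF01 values with their explained
variance.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .bayes import BayesResult, InclusionBF, SequentialBF
from .pipeline import (
    CONDITIONS,
    CONDITION_SETS,
    MEASURES,
    BatteryResult,
    within_subject_errorbars,
)

__all__ = ["render_report"]

_COND_COLORS = {
    "combined": "0.4",
    "vertical": "tab:red",
    "horizontal": "tab:blue",
    "oblique": "tab:green",
}


def _bayes_result_dict(res: BayesResult) -> dict:
    d = {
        "bf10": res.bf10,
        "bf01": res.bf01,
        "effect": res.effect,
        "sided": res.sided,
        "prior_scale": res.prior_scale,
        "method": res.method,
        "interpretation": res.interpretation,
    }
    if res.mc_iterations is not None:
        d["mc_iterations"] = res.mc_iterations
        d["mc_error"] = res.mc_error
    d.update({k: v for k, v in res.extra.items()})
    return d


def _inclusion_dict(inc: InclusionBF) -> dict:
    return {
        "per_effect": {k: _bayes_result_dict(v) for k, v in inc.per_effect.items()},
        "model_log_bf": inc.model_log_bf,
        "model_posteriors": inc.model_posteriors,
        "mc_iterations": inc.mc_iterations,
        "fixed_scale": inc.fixed_scale,
        "random_scale": inc.random_scale,
        "subject_treatment": inc.subject_treatment,
        "n_dropped_subjects": inc.n_dropped_subjects,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if math.isnan(f):
            return None
        if math.isinf(f):
            return "inf" if f > 0 else "-inf"
        return f
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def render_report(
    oblique: dict,
    batteries: Optional[BatteryResult],
    outdir,
    seed: Optional[int] = None,
    exclusion_log: Optional[list] = None,
    config: Optional[dict] = None,
) -> dict:
    """Write report.json and the figure files; return the JSON payload."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    payload = {
        "seed": seed,
        "config": config or {},
        "exclusions": exclusion_log or [],
        "chance_tests": {
            k: _bayes_result_dict(v) for k, v in oblique["chance_tests"].items()
        },
        "rm_anovas": {k: _inclusion_dict(v) for k, v in oblique["rm_anovas"].items()},
        "verdict_table": oblique["verdict_table"],
        "condition_posthocs": {
            m: [_bayes_result_dict(r) for r in lst]
            for m, lst in oblique["condition_posthocs"].items()
        },
        "duration_posthoc_matrix": oblique["duration_posthoc_matrix"],
        "group_means": oblique["summaries"]["by_condition"]
        .groupby("condition")[list(MEASURES)]
        .mean()
        .reset_index(),
    }
    if oblique.get("sequential") is not None:
        seq: SequentialBF = oblique["sequential"]
        payload["sequential"] = {
            "effect": seq.effect,
            "threshold": seq.threshold,
            "n_min": seq.n_min,
            "crossing_n": seq.crossing_n,
            "trajectory": seq.trajectory,
        }
    if batteries is not None:
        payload["batteries"] = {
            "between_subject": batteries.between_subject,
            "order_anovas": batteries.order_anovas,
            "within_subject_group": batteries.within_subject_group,
            "counts": {
                "between_subject": int(len(batteries.between_subject)),
                "order_anovas": int(len(batteries.order_anovas)),
                "within_subject_per_participant": int(
                    batteries.within_subject.groupby("participant").size().iloc[0]
                )
                if len(batteries.within_subject)
                else 0,
            },
        }
    payload = _jsonable(payload)
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)

    _fig_accuracy_distributions(oblique, outdir / "fig_accuracy_distributions.png")
    if oblique.get("sequential") is not None:
        _fig_sequential(oblique["sequential"], outdir / "fig_sequential_bf.png")
    _fig_condition_means(oblique, outdir / "fig_condition_means.png")
    _fig_duration_heatmap(
        oblique["duration_posthoc_matrix"], outdir / "fig_duration_bf_heatmap.png"
    )
    if batteries is not None:
        _fig_battery_violins(batteries, outdir / "fig_battery_violins.png")

    # Flat tables alongside the JSON.
    oblique["summaries"]["by_condition"].to_csv(
        outdir / "participant_measures.csv", index=False
    )
    oblique["duration_posthoc_matrix"].to_csv(outdir / "duration_posthoc_bf10.csv")
    return payload


def _fig_accuracy_distributions(oblique: dict, path: Path) -> None:
    by_cond = oblique["summaries"]["by_condition"]
    fig, ax = plt.subplots(figsize=(6, 4))
    rng = np.random.default_rng(0)  # cosmetic jitter only
    for i, cond in enumerate(CONDITION_SETS):
        vals = by_cond.loc[by_cond["condition"] == cond, "accuracy"].dropna()
        x = i + rng.uniform(-0.12, 0.12, len(vals))
        ax.plot(x, vals, "o", ms=4, alpha=0.6, color=_COND_COLORS[cond])
        ax.hlines(vals.mean(), i - 0.25, i + 0.25, color=_COND_COLORS[cond])
        bf = oblique["chance_tests"][f"accuracy:{cond}"].bf10
        ax.annotate(f"BF10={bf:.3g}", (i, 102), ha="center", fontsize=8)
    ax.axhline(50, ls="--", color="k", lw=0.8)
    ax.set_xticks(range(len(CONDITION_SETS)), CONDITION_SETS)
    ax.set_ylabel("% correct")
    ax.set_ylim(30, 108)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig_sequential(seq: SequentialBF, path: Path) -> None:
    df = seq.as_frame()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(df["n_participants"], df["bf"], "-o", ms=3)
    ax.axhline(seq.threshold, color="tab:green", ls="--", lw=0.8)
    ax.axhline(1 / seq.threshold, color="tab:red", ls="--", lw=0.8)
    ax.axvline(seq.n_min, color="0.5", ls=":", lw=0.8)
    ax.set_yscale("log")
    ax.set_xlabel("participants recruited")
    ax.set_ylabel(f"BF ({seq.effect})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig_condition_means(oblique: dict, path: Path) -> None:
    by_cond = oblique["summaries"]["by_condition"]
    cells = by_cond[by_cond["condition"] != "combined"][
        ["participant", "condition", "accuracy"]
    ].rename(columns={"accuracy": "value"})
    bars = within_subject_errorbars(cells.dropna())
    bars = bars.set_index("condition").loc[list(CONDITIONS)].reset_index()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(
        bars["condition"],
        bars["mean"],
        yerr=bars["within_subject_se"],
        color=[_COND_COLORS[c] for c in bars["condition"]],
        alpha=0.7,
        capsize=4,
    )
    ax.axhline(50, ls="--", color="k", lw=0.8)
    ax.set_ylabel("% correct (within-subject SE)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig_duration_heatmap(matrix: pd.DataFrame, path: Path) -> None:
    with np.errstate(divide="ignore"):
        logbf = np.log10(matrix.to_numpy(dtype=float))
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    im = ax.imshow(logbf, cmap="coolwarm", vmin=-2, vmax=4)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns)
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    ax.set_xlabel("duration level")
    ax.set_ylabel("duration level")
    fig.colorbar(im, label="log10 BF10 (confidence difference)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig_battery_violins(batteries: BatteryResult, path: Path) -> None:
    groups = []
    labels = []
    for var, sub in batteries.between_subject.groupby("variable"):
        groups.append(np.log10(sub["bf01"].dropna().to_numpy()))
        labels.append(var)
    if len(batteries.order_anovas):
        groups.append(np.log10(batteries.order_anovas["bf01"].dropna().to_numpy()))
        labels.append("condition order")
    for var, sub in batteries.within_subject_group.groupby("variable"):
        groups.append(np.log10(sub["bf01"].dropna().to_numpy()))
        labels.append(f"{var} (within)")
    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(7, 6), sharex=True, height_ratios=[1, 2]
    )
    r2 = []
    for lab in labels:
        if lab.endswith("(within)"):
            sub = batteries.within_subject_group[
                batteries.within_subject_group["variable"] == lab.split(" ")[0]
            ]
            r2.append(sub["median_r2"].dropna().to_numpy() * 100)
        elif lab == "condition order":
            r2.append(np.array([]))
        else:
            sub = batteries.between_subject[
                batteries.between_subject["variable"] == lab
            ]
            r2.append(sub["r2"].dropna().to_numpy() * 100)
    for i, vals in enumerate(r2):
        if len(vals):
            ax0.plot(np.full(len(vals), i + 1), vals, "k*", ms=5, alpha=0.6)
    ax0.set_ylabel("R$^2$ (%)")
    ax0.set_ylim(0, 100)
    parts = [g for g in groups if len(g)]
    pos = [i + 1 for i, g in enumerate(groups) if len(g)]
    if parts:
        ax1.violinplot(parts, positions=pos, showmedians=True)
    ax1.axhline(np.log10(3), color="tab:red", lw=0.8)
    ax1.axhline(-np.log10(3), color="tab:red", lw=0.8)
    ax1.set_xticks(range(1, len(labels) + 1), labels, rotation=20, ha="right")
    ax1.set_ylabel("log10 BF01")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
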
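"""Synthetic observers for the 2IFC tactile-motion task.

No observer model is fitted anywhere in the analysis, so the
generator here is a deliberately minimal stand-in whose only job is
to realize chosen per-condition accuracies, metacognitive
sensitivities (target type-II AROC) and an inverted-U
confidence-by-duration profile, with the large between-participant
heterogeneity the task exhibits:

* correctness is Bernoulli with a per-condition probability ``p_c``
  (duration-independent by default - stimulus duration moves
  confidence, not accuracy);
* confidence comes from a two-distribution ordinal model: a latent
  evidence variable is normal with mean +m/2 on correct trials and
  -m/2 on incorrect trials (unit variance), shifted by a
  duration-dependent confidence drive, and cut at four fixed
  thresholds into ratings 1-5.  ``m`` is the metacognitive
  separation; the mapping m <-> expected AROC is available in closed
  form for calibration.

Defaults emulate the study conditions: 42 participants, cardinal
accuracy above oblique accuracy (combined mean near 60%), group mean
AROC near 0.57, mean confidence near 3 with the highest ratings at
intermediate durations, and wide between-participant spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .design import Schedule

__all__ = [
    "PopulationSpec",
    "ObserverParams",
    "Cohort",
    "sample_cohort",
    "simulate_responses",
    "inject_exclusion_case",
    "expected_aroc",
    "metacog_separation_for_aroc",
    "default_duration_profile",
]

DEFAULT_THRESHOLDS = (-0.9, -0.1, 0.7, 1.5)


def default_duration_profile(
    durations_ms: Sequence,
    peak_ms: float = 1280.0,
    log_width: float = 1.1,
    low: float = 0.55,
    high: float = 1.45,
) -> np.ndarray:
    """Inverted-U confidence multiplier over the duration grid.

    A Gaussian bump in log duration, peaking near the middle of the
    grid (confidence is highest for stimuli of roughly 0.7-2.4 s and
    lowest at the 200 ms and 8 s extremes).
    """
    d = np.log(np.asarray(durations_ms, dtype=float))
    bump = np.exp(-0.5 * ((d - math.log(peak_ms)) / log_width) ** 2)
    return low + (high - low) * bump


@dataclass
class PopulationSpec:
    """Population distributions the cohort is drawn from.

    Accuracies are logit-normal per condition (one shared
    between-subject offset plus a small condition-specific jitter),
    truncated below at chance.  Metacognitive separation is set per
    observer by inverting the closed-form AROC mapping at a normally
    distributed target AROC.
    """

    p_vertical: float = 0.63
    p_horizontal: float = 0.63
    p_oblique: float = 0.56
    sd_logit_between: float = 0.40
    sd_logit_condition: float = 0.12
    aroc_mean: float = 0.57
    aroc_sd: float = 0.10
    conf_drive_mean: float = 0.35
    conf_drive_sd: float = 0.35
    thresholds: tuple = DEFAULT_THRESHOLDS
    lapse_rate: float = 0.0
    duration_profile_peak_ms: float = 1280.0
    duration_profile_log_width: float = 1.1
    duration_profile_low: float = 0.55
    duration_profile_high: float = 1.45
    accuracy_duration_slope: float = 0.0  # switch for power studies; 0 = null effect
    age_mean: float = 24.2
    age_sd: float = 5.0
    age_range: tuple = (19.0, 40.0)
    hand_size_mean_cm: float = 18.5
    hand_size_sd_cm: float = 1.2
    finger_size_mean_cm: float = 7.3
    finger_size_sd_cm: float = 0.6
    hand_temp_mean_c: float = 30.5
    hand_temp_sd_c: float = 1.2
    body_temp_mean_c: float = 36.6
    body_temp_sd_c: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "sd_logit_between",
            "sd_logit_condition",
            "aroc_sd",
            "conf_drive_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for p in (self.p_vertical, self.p_horizontal, self.p_oblique):
            if not 0.5 <= p < 1.0:
                raise ValueError("condition accuracies must lie in [0.5, 1)")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if not 0.5 <= self.aroc_mean < 1.0:
            raise ValueError("aroc_mean must lie in [0.5, 1)")
        th = np.asarray(self.thresholds, dtype=float)
        if not (np.diff(th) > 0).all():
            raise ValueError("confidence thresholds must be strictly increasing")

    @property
    def p_by_condition(self) -> dict:
        return {
            "vertical": self.p_vertical,
            "horizontal": self.p_horizontal,
            "oblique": self.p_oblique,
        }


@dataclass
class ObserverParams:
    """Generative parameters of one synthetic participant."""

    p_by_condition: dict
    metacog_m: float
    conf_drive: float
    thresholds: tuple
    duration_profile: np.ndarray
    lapse_rate: float
    age_years: float
    hand_size_cm: float
    finger_size_cm: float
    base_hand_temp_c: float
    base_body_temp_c: float

    def __post_init__(self) -> None:
        th = np.asarray(self.thresholds, dtype=float)
        if not (np.diff(th) > 0).all():
            raise ValueError("thresholds must be strictly increasing")
        if self.metacog_m < 0:
            raise ValueError("metacognitive separation must be >= 0")
        if np.any(np.asarray(self.duration_profile) <= 0):
            raise ValueError("duration profile must be positive")
        for c, p in self.p_by_condition.items():
            if not (0.5 - self.lapse_rate) <= p <= 1.0:
                raise ValueError(f"p[{c}]={p} outside [0.5 - lapse, 1]")

    @property
    def palm_size_cm(self) -> float:
        return self.hand_size_cm - self.finger_size_cm


@dataclass
class Cohort:
    observers: dict  # participant_id -> ObserverParams
    population: PopulationSpec
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.observers)


# ---------------------------------------------------------------------------
# AROC calibration (closed form for the two-distribution ordinal model)
# ---------------------------------------------------------------------------

def _rating_pmf(means: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """P(rating = 1..K) when the latent is N(mean, 1) cut at thresholds.

    Vectorized over a vector of means; returns shape (n_means, K).
    """
    means = np.atleast_1d(np.asarray(means, dtype=float))
    cdf = special.ndtr(thresholds[None, :] - means[:, None])
    cdf = np.concatenate(
        [np.zeros((means.size, 1)), cdf, np.ones((means.size, 1))], axis=1
    )
    return np.diff(cdf, axis=1)


def expected_aroc(
    m: float,
    thresholds: Sequence = DEFAULT_THRESHOLDS,
    shifts: Sequence = (0.0,),
    weights: Optional[Sequence] = None,
) -> float:
    """Exact type-II AROC of the generative confidence model.

    ``shifts`` are the duration-profile drives added to the latent on
    both correct and incorrect trials (the pooled rating distributions
    are mixtures over them, weighted by ``weights``).  The returned
    value is the tie-aware rank probability that a correct trial's
    rating exceeds an incorrect trial's, which is what the trapezoidal
    type-II AROC estimator converges to.
    """
    th = np.asarray(thresholds, dtype=float)
    shifts = np.asarray(shifts, dtype=float)
    w = np.full(shifts.size, 1.0 / shifts.size) if weights is None else (
        np.asarray(weights, dtype=float) / np.sum(weights)
    )
    pc = w @ _rating_pmf(shifts + m / 2.0, th)
    pi = w @ _rating_pmf(shifts - m / 2.0, th)
    cum_c = np.concatenate([[0.0], np.cumsum(pc)])
    # P(correct rating > j) + half-credit ties
    auc = 0.0
    for j in range(pi.size):
        auc += pi[j] * ((1.0 - cum_c[j + 1]) + 0.5 * pc[j])
    return float(auc)


def metacog_separation_for_aroc(
    target_aroc: float,
    thresholds: Sequence = DEFAULT_THRESHOLDS,
    shifts: Sequence = (0.0,),
    weights: Optional[Sequence] = None,
) -> float:
    """Invert the m <-> AROC mapping by bracketed root finding."""
    if not 0.5 <= target_aroc < 1.0:
        raise ValueError("target AROC must lie in [0.5, 1)")
    if target_aroc == 0.5:
        return 0.0
    f = lambda m: expected_aroc(m, thresholds, shifts, weights) - target_aroc
    return float(optimize.brentq(f, 0.0, 20.0, xtol=1e-8))


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

def sample_cohort(
    n: int,
    population: Optional[PopulationSpec] = None,
    seed: Optional[int] = None,
    durations_ms: Optional[Sequence] = None,
) -> Cohort:
    """Draw ``n`` synthetic observers from the population distributions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pop = population if population is not None else PopulationSpec()
    if durations_ms is None:
        durations_ms = np.geomspace(200.0, 8000.0, 10)
    profile = default_duration_profile(
        durations_ms,
        peak_ms=pop.duration_profile_peak_ms,
        log_width=pop.duration_profile_log_width,
        low=pop.duration_profile_low,
        high=pop.duration_profile_high,
    )
    rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, 11]))
    observers: dict[int, ObserverParams] = {}
    for pid in range(1, n + 1):
        u = rng.normal(0.0, pop.sd_logit_between)
        p_by_cond = {}
        for cond, p0 in pop.p_by_condition.items():
            z = _logit(p0) + u + rng.normal(0.0, pop.sd_logit_condition)
            p_by_cond[cond] = float(np.clip(_expit(z), 0.5, 0.995))
        drive = rng.normal(pop.conf_drive_mean, pop.conf_drive_sd)
        target = float(
            np.clip(rng.normal(pop.aroc_mean, pop.aroc_sd), 0.502, 0.95)
        )
        m = metacog_separation_for_aroc(
            target, pop.thresholds, shifts=drive * profile
        )
        age = float(np.clip(rng.normal(pop.age_mean, pop.age_sd), *pop.age_range))
        hand = rng.normal(pop.hand_size_mean_cm, pop.hand_size_sd_cm)
        finger = rng.normal(pop.finger_size_mean_cm, pop.finger_size_sd_cm)
        observers[pid] = ObserverParams(
            p_by_condition=p_by_cond,
            metacog_m=m,
            conf_drive=float(drive),
            thresholds=tuple(pop.thresholds),
            duration_profile=profile.copy(),
            lapse_rate=pop.lapse_rate,
            age_years=age,
            hand_size_cm=float(hand),
            finger_size_cm=float(finger),
            base_hand_temp_c=float(rng.normal(pop.hand_temp_mean_c, pop.hand_temp_sd_c)),
            base_body_temp_c=float(rng.normal(pop.body_temp_mean_c, pop.body_temp_sd_c)),
        )
    return Cohort(observers=observers, population=pop, seed=seed)


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _expit(z) -> float:
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# Response simulation
# ---------------------------------------------------------------------------

def simulate_responses(
    schedule: Schedule,
    cohort: Cohort,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate one trial table (long format) for a scheduled cohort.

    Crashed trials produce no row.  Training trials are answered but
    carry no confidence rating (the task collects confidence only in
    experimental blocks).  Per-block hand and body temperatures are
    drawn around each observer's baseline.
    """
    missing = {
        t.participant_id for t in schedule.trials
    } - set(cohort.observers.keys())
    if missing:
        raise ValueError(f"schedule references observers absent from cohort: {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, 23]))
    pop = cohort.population

    block_temps: dict[tuple, tuple] = {}
    rows = []
    for t in schedule.trials:
        if t.crashed:
            continue
        obs = cohort.observers[t.participant_id]
        cond = t.condition.axis_label
        p = obs.p_by_condition[cond]
        if pop.accuracy_duration_slope != 0.0 and t.duration_level >= 0:
            centred = t.duration_level - (schedule.grid.n_levels - 1) / 2.0
            p = float(np.clip(
                _expit(_logit(p) + pop.accuracy_duration_slope * centred), 0.02, 0.995
            ))
        if obs.lapse_rate > 0 and rng.random() < obs.lapse_rate:
            correct = rng.random() < 0.5
        else:
            correct = rng.random() < p
        response = t.correct_interval if correct else 3 - t.correct_interval

        if t.is_training:
            confidence = np.nan
        else:
            w = obs.duration_profile[t.duration_level]
            evid = (obs.metacog_m / 2.0 if correct else -obs.metacog_m / 2.0)
            latent = obs.conf_drive * w + evid + rng.normal()
            confidence = 1 + int(np.sum(latent > np.asarray(obs.thresholds)))

        key = (t.participant_id, t.block_index)
        if key not in block_temps:
            block_temps[key] = (
                obs.base_hand_temp_c + rng.normal(0.0, 0.8),
                obs.base_body_temp_c + rng.normal(0.0, 0.2),
            )
        hand_t, body_t = block_temps[key]
        rows.append(
            {
                "participant": t.participant_id,
                "session": t.session,
                "block": t.block_index,
                "condition": cond,
                "duration_ms": t.duration_ms,
                "duration_level": t.duration_level,
                "correct_interval": t.correct_interval,
                "trial_in_condition": t.trial_in_condition,
                "is_training": t.is_training,
                "is_topup": t.is_topup,
                "response_interval": int(response),
                "correct": bool(correct),
                "confidence": confidence,
                "hand_temp_c": hand_t,
                "body_temp_c": body_t,
                "age_years": obs.age_years,
                "palm_size_cm": obs.palm_size_cm,
                "hand_size_cm": obs.hand_size_cm,
                "finger_size_cm": obs.finger_size_cm,
                "condition_order": "-".join(
                    schedule.condition_orders.get(t.participant_id, ())
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pathology injection for exclusion-rule testing
# ---------------------------------------------------------------------------

def inject_exclusion_case(
    records: pd.DataFrame,
    mode: str = "none",
    participant: Optional[int] = None,
    seed: Optional[int] = None,
    share: float = 0.97,
) -> pd.DataFrame:
    """Return a dataset variant with one participant showing a named pathology.

    Modes: ``none`` (identity), ``single-key`` (the participant presses
    one response key on ``share`` of trials, mimicking the excluded
    real participant), ``mapping-flip`` (responses inverted, producing
    a below-chance scorer).
    """
    if mode == "none":
        return records.copy()
    df = records.copy()
    pid = participant if participant is not None else int(df["participant"].min())
    mask = df["participant"] == pid
    if not mask.any():
        raise ValueError(f"participant {pid} not in records")
    if mode == "single-key":
        rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, 31]))
        idx = df.index[mask]
        hit = idx[rng.random(idx.size) < share]
        df.loc[hit, "response_interval"] = 1
        df.loc[mask, "correct"] = (
            df.loc[mask, "response_interval"] == df.loc[mask, "correct_interval"]
        )
    elif mode == "mapping-flip":
        df.loc[mask, "response_interval"] = 3 - df.loc[mask, "response_interval"]
        df.loc[mask, "correct"] = ~df.loc[mask, "correct"].astype(bool)
    else:
        raise ValueError(f"unknown exclusion mode {mode!r}")
    return df
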
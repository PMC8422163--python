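"""Trial schedule generation for the two-interval forced-choice motion task.

The task probes the tactile oblique effect on the palm: three motion
axes (vertical 0-180, horizontal 90-270, oblique 45-225), each run as
its own block of two-interval forced-choice (2IFC) trials.  Stimulus
duration varies over a 10-level logarithmic grid from 200 ms to 8 s,
with every duration presented the same number of times per block.
Condition order is counterbalanced across participants over all six
permutations, and dot start positions for trial *n* are shared across
the three conditions within a participant so that condition effects
cannot be driven by where the dots happened to appear.

A device-crash top-up rule appends replacement trials so each
condition reaches a minimum completed-trial floor (200 by default).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .stimulus import PalmRegion, sample_start_points

__all__ = [
    "Condition",
    "DurationGrid",
    "TrialSpec",
    "Schedule",
    "DEFAULT_CONDITIONS",
    "make_duration_grid",
    "build_schedule",
    "apply_crash_topup",
    "schedule_to_frame",
]


@dataclass(frozen=True)
class Condition:
    """One motion axis with the direction the participant must identify."""

    axis_label: str
    axis_degrees: tuple
    target_direction_label: str

    def __post_init__(self) -> None:
        a, b = self.axis_degrees
        if (b - a) % 360 != 180:
            raise ValueError("axis directions must be opposed (180 deg apart)")


VERTICAL = Condition("vertical", (0, 180), "downwards")
HORIZONTAL = Condition("horizontal", (90, 270), "rightwards")
OBLIQUE = Condition("oblique", (45, 225), "oblique-downwards")

#: The study's three conditions.
DEFAULT_CONDITIONS = (VERTICAL, HORIZONTAL, OBLIQUE)

_BY_LABEL = {c.axis_label: c for c in DEFAULT_CONDITIONS}


def condition_by_label(label: str) -> Condition:
    return _BY_LABEL[label]


@dataclass(frozen=True)
class DurationGrid:
    """Logarithmically spaced stimulus durations (ms)."""

    values_ms: tuple

    @property
    def n_levels(self) -> int:
        return len(self.values_ms)

    @property
    def min_ms(self) -> float:
        return self.values_ms[0]

    @property
    def max_ms(self) -> float:
        return self.values_ms[-1]

    def level_of(self, duration_ms: float) -> int:
        """0-based index of a grid duration."""
        arr = np.asarray(self.values_ms)
        i = int(np.argmin(np.abs(arr - duration_ms)))
        if not math.isclose(arr[i], duration_ms, rel_tol=1e-9):
            raise ValueError(f"{duration_ms} is not on the grid")
        return i


def make_duration_grid(
    n_levels: int = 10, min_ms: float = 200.0, max_ms: float = 8000.0
) -> DurationGrid:
    """Log-spaced duration grid inclusive of both endpoints.

    Values are kept at full floating precision; consecutive values
    share a constant ratio ``(max_ms / min_ms) ** (1 / (n_levels - 1))``.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if not (0 < min_ms < max_ms):
        raise ValueError("require 0 < min_ms < max_ms")
    vals = np.geomspace(min_ms, max_ms, n_levels)
    vals[0], vals[-1] = min_ms, max_ms  # exact endpoints
    return DurationGrid(tuple(float(v) for v in vals))


@dataclass
class TrialSpec:
    """One scheduled 2IFC trial (pre-response)."""

    participant_id: int
    session: int
    block_index: int
    condition: Condition
    duration_ms: float
    duration_level: int
    correct_interval: int
    trial_in_condition: int
    start_points: np.ndarray
    is_training: bool = False
    crashed: bool = False
    is_topup: bool = False


@dataclass
class Schedule:
    """Ordered trials plus the design parameters that generated them."""

    trials: list
    condition_orders: dict
    grid: DurationGrid
    blocks_per_condition: int = 5
    trials_per_block: int = 40
    reps_per_duration: int = 4
    topup_floor: int = 200
    seed: Optional[int] = None
    region: PalmRegion = field(default_factory=PalmRegion)
    n_dots: int = 6
    dot_diameter_mm: float = 8.5

    def completed(self) -> list:
        return [t for t in self.trials if not t.crashed]

    def config(self) -> dict:
        """Design parameters as a plain serializable mapping."""
        return {
            "n_participants": len(self.condition_orders),
            "conditions": [c.axis_label for c in DEFAULT_CONDITIONS],
            "blocks_per_condition": self.blocks_per_condition,
            "trials_per_block": self.trials_per_block,
            "reps_per_duration": self.reps_per_duration,
            "duration_grid_ms": list(self.grid.values_ms),
            "topup_floor": self.topup_floor,
            "seed": self.seed,
            "region_width_cm": self.region.width_cm,
            "n_dots": self.n_dots,
            "dot_diameter_mm": self.dot_diameter_mm,
        }


def _start_points_for(
    seed: Optional[int],
    participant_id: int,
    trial_in_condition: int,
    n_dots: int,
    region: PalmRegion,
    dot_diameter_mm: float,
) -> np.ndarray:
    """Start positions s_n: a pure function of (seed, participant, trial index).

    Conditions never enter the key, so matched trial indices share
    byte-identical start configurations across the three conditions.
    """
    # training trials carry negative indices; map them into their own
    # non-negative key range (SeedSequence entropy must be non-negative)
    idx_key = (
        trial_in_condition
        if trial_in_condition >= 0
        else 1_000_000 - trial_in_condition
    )
    ss = np.random.SeedSequence([0 if seed is None else seed, participant_id, idx_key])
    return sample_start_points(
        n_dots, region, dot_diameter_mm, rng=np.random.default_rng(ss)
    )


def _balanced_intervals(n: int, rng: np.random.Generator) -> np.ndarray:
    """n interval labels with counts of 1s and 2s equal up to rounding."""
    half = n // 2
    arr = np.array([1] * half + [2] * (n - half))
    rng.shuffle(arr)
    return arr


def build_schedule(
    n_participants: int,
    conditions: Sequence[Condition] = DEFAULT_CONDITIONS,
    blocks_per_condition: int = 5,
    grid: Optional[DurationGrid] = None,
    reps_per_duration: int = 4,
    seed: Optional[int] = None,
    topup_floor: int = 200,
    include_training: bool = False,
    region: PalmRegion = PalmRegion(),
    n_dots: int = 6,
    dot_diameter_mm: float = 8.5,
) -> Schedule:
    """Build the full trial schedule for a cohort.

    Each block holds one condition and ``reps_per_duration`` trials of
    every grid duration in randomized order; correct intervals are
    balanced within block.  Condition orders cycle through all six
    permutations (shuffled once per cohort seed) so that over ``n``
    participants the permutation counts differ by at most one.
    Training blocks (6 one-second feedback trials per condition) are
    generated only on request and flagged ``is_training``.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if blocks_per_condition < 1 or reps_per_duration < 1:
        raise ValueError("counts must be >= 1")
    if grid is None:
        grid = make_duration_grid()

    rng = np.random.default_rng(np.random.SeedSequence([1 if seed is None else seed, 7]))
    perms = list(itertools.permutations(range(len(conditions))))
    rng.shuffle(perms)

    trials_per_block = grid.n_levels * reps_per_duration
    trials: list[TrialSpec] = []
    condition_orders: dict[int, tuple] = {}

    for pid in range(1, n_participants + 1):
        order_idx = perms[(pid - 1) % len(perms)]
        order = tuple(conditions[i] for i in order_idx)
        condition_orders[pid] = tuple(c.axis_label for c in order)
        p_rng = np.random.default_rng(
            np.random.SeedSequence([2 if seed is None else seed, pid])
        )
        # s_n is shared across the three conditions; cache per trial index
        # so the (identical) positions are computed once, not once per axis.
        sp_cache: dict[int, np.ndarray] = {}

        def start_points(n_idx: int) -> np.ndarray:
            if n_idx not in sp_cache:
                sp_cache[n_idx] = _start_points_for(
                    seed, pid, n_idx, n_dots, region, dot_diameter_mm
                )
            return sp_cache[n_idx]

        trial_counter = {c.axis_label: 0 for c in conditions}
        block_counter = 0

        if include_training:
            for cond in order:
                ints = _balanced_intervals(6, p_rng)
                for k in range(6):
                    trials.append(
                        TrialSpec(
                            participant_id=pid,
                            session=1,
                            block_index=-1,
                            condition=cond,
                            duration_ms=1000.0,
                            duration_level=-1,
                            correct_interval=int(ints[k]),
                            trial_in_condition=-(k + 1),
                            start_points=start_points(-(k + 1)),
                            is_training=True,
                        )
                    )

        # Session 1 holds the first two experimental blocks of each
        # condition, session 2 the remaining blocks.
        s1_blocks = min(2, blocks_per_condition)
        for session, block_range in (
            (1, range(s1_blocks)),
            (2, range(s1_blocks, blocks_per_condition)),
        ):
            for cond in order:
                for _b in block_range:
                    durs = np.repeat(grid.values_ms, reps_per_duration)
                    p_rng.shuffle(durs)
                    ints = _balanced_intervals(trials_per_block, p_rng)
                    for k in range(trials_per_block):
                        n_idx = trial_counter[cond.axis_label]
                        trial_counter[cond.axis_label] += 1
                        trials.append(
                            TrialSpec(
                                participant_id=pid,
                                session=session,
                                block_index=block_counter,
                                condition=cond,
                                duration_ms=float(durs[k]),
                                duration_level=grid.level_of(float(durs[k])),
                                correct_interval=int(ints[k]),
                                trial_in_condition=n_idx,
                                start_points=start_points(n_idx),
                            )
                        )
                    block_counter += 1

    return Schedule(
        trials=trials,
        condition_orders=condition_orders,
        grid=grid,
        blocks_per_condition=blocks_per_condition,
        trials_per_block=trials_per_block,
        reps_per_duration=reps_per_duration,
        topup_floor=topup_floor,
        seed=seed,
        region=region,
        n_dots=n_dots,
        dot_diameter_mm=dot_diameter_mm,
    )


def apply_crash_topup(schedule: Schedule, crashed_trials: Iterable[int]) -> Schedule:
    """Mark crashed trials and append replacements at the end.

    Replacement trials keep the crashed trial's participant and
    condition; their durations are redrawn to restore the per-duration
    balance (each appended trial takes a duration that is currently
    under-represented among that participant-condition's completed
    experimental trials).  Idempotent when nothing crashed.
    """
    crashed = sorted(set(int(i) for i in crashed_trials))
    n = len(schedule.trials)
    for i in crashed:
        if not (0 <= i < n):
            raise IndexError(f"crashed trial index {i} out of range")
    if not crashed:
        return schedule

    new_trials = [replace(t) for t in schedule.trials]
    for i in crashed:
        new_trials[i].crashed = True

    rng = np.random.default_rng(
        np.random.SeedSequence([3 if schedule.seed is None else schedule.seed, 999])
    )
    grid = schedule.grid
    # Deficits per (participant, condition, duration level).
    target_per_level = schedule.blocks_per_condition * schedule.reps_per_duration
    groups: dict[tuple, list] = {}
    for t in new_trials:
        if t.is_training:
            continue
        groups.setdefault((t.participant_id, t.condition.axis_label), []).append(t)

    appended: list[TrialSpec] = []
    for (pid, cond_label), ts in sorted(groups.items()):
        cond = ts[0].condition
        completed_per_level = np.zeros(grid.n_levels, dtype=int)
        max_idx = -1
        max_block = -1
        for t in ts:
            if not t.crashed:
                completed_per_level[t.duration_level] += 1
            max_idx = max(max_idx, t.trial_in_condition)
            max_block = max(max_block, t.block_index)
        deficits = target_per_level - completed_per_level
        levels = np.repeat(np.arange(grid.n_levels), np.clip(deficits, 0, None))
        rng.shuffle(levels)
        ints = _balanced_intervals(len(levels), rng)
        for j, lev in enumerate(levels):
            max_idx += 1
            appended.append(
                TrialSpec(
                    participant_id=pid,
                    session=2,
                    block_index=max_block + 1,
                    condition=cond,
                    duration_ms=grid.values_ms[lev],
                    duration_level=int(lev),
                    correct_interval=int(ints[j]),
                    trial_in_condition=max_idx,
                    start_points=_start_points_for(
                        schedule.seed,
                        pid,
                        max_idx,
                        schedule.n_dots,
                        schedule.region,
                        schedule.dot_diameter_mm,
                    ),
                    is_topup=True,
                )
            )
    return replace(schedule, trials=new_trials + appended)


def _serialize_points(pts: np.ndarray) -> str:
    return ";".join(f"{x:.17g}:{y:.17g}" for x, y in np.asarray(pts))


def _parse_points(s: str) -> np.ndarray:
    return np.array([[float(v) for v in pair.split(":")] for pair in s.split(";")])


def schedule_to_frame(schedule: Schedule) -> pd.DataFrame:
    """Flatten a schedule to one row per trial (delimited-text friendly)."""
    rows = []
    for i, t in enumerate(schedule.trials):
        rows.append(
            {
                "trial_index": i,
                "participant": t.participant_id,
                "session": t.session,
                "block": t.block_index,
                "condition": t.condition.axis_label,
                "axis_low_deg": t.condition.axis_degrees[0],
                "axis_high_deg": t.condition.axis_degrees[1],
                "target_direction": t.condition.target_direction_label,
                "duration_ms": t.duration_ms,
                "duration_level": t.duration_level,
                "correct_interval": t.correct_interval,
                "trial_in_condition": t.trial_in_condition,
                "is_training": t.is_training,
                "crashed": t.crashed,
                "is_topup": t.is_topup,
                "start_points": _serialize_points(t.start_points),
            }
        )
    return pd.DataFrame(rows)


def schedule_from_frame(df: pd.DataFrame, config: dict) -> Schedule:
    """Rebuild a Schedule from its flattened table plus its config block."""
    grid = DurationGrid(tuple(config["duration_grid_ms"]))
    trials = []
    for _, r in df.sort_values("trial_index").iterrows():
        trials.append(
            TrialSpec(
                participant_id=int(r["participant"]),
                session=int(r["session"]),
                block_index=int(r["block"]),
                condition=condition_by_label(r["condition"]),
                duration_ms=float(r["duration_ms"]),
                duration_level=int(r["duration_level"]),
                correct_interval=int(r["correct_interval"]),
                trial_in_condition=int(r["trial_in_condition"]),
                start_points=_parse_points(r["start_points"]),
                is_training=bool(r["is_training"]),
                crashed=bool(r["crashed"]),
                is_topup=bool(r["is_topup"]),
            )
        )
    orders: dict[int, tuple] = {}
    exp = df[~df["is_training"]]
    for pid, sub in exp.groupby("participant"):
        seen = sub.sort_values("trial_index")["condition"].drop_duplicates()
        orders[int(pid)] = tuple(seen)
    return Schedule(
        trials=trials,
        condition_orders=orders,
        grid=grid,
        blocks_per_condition=int(config["blocks_per_condition"]),
        trials_per_block=int(config["trials_per_block"]),
        reps_per_duration=int(config["reps_per_duration"]),
        topup_floor=int(config["topup_floor"]),
        seed=config.get("seed"),
        region=PalmRegion(config["region_width_cm"], config["region_width_cm"]),
        n_dots=int(config["n_dots"]),
        dot_diameter_mm=float(config["dot_diameter_mm"]),
    )
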
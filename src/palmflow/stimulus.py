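"""Coherent-motion dot stimulus simulation on a palm-bounded region.

The stimulus is a field of tactile dots that all share one velocity
(a tactile analogue of the classic random dot kinetogram).  Dots are
confined to a square region matched to the palm; any dot whose disc
would cross the region boundary is respawned at a pseudorandom
position that does not overlap any other dot, so the percept is a
continuous flow for arbitrarily long durations.

Coordinate convention: origin at the lower-left (ulnar-proximal)
corner, ``x`` runs medial-to-lateral, ``y`` proximal-to-distal, units
are cm.  Directions are measured in degrees from the +y (distal) axis
rotating towards +x, so 0-180 is the vertical axis, 90-270 the
horizontal axis and 45-225 the oblique axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PalmRegion",
    "StimulusSpec",
    "Trajectory",
    "RespawnEvent",
    "MotionSummary",
    "PackingError",
    "sample_start_points",
    "simulate_trajectory",
    "summarize_motion",
    "ALLOWED_DIRECTIONS",
]

#: Directions used in the task: the three axes, each with two opposed directions.
ALLOWED_DIRECTIONS = (0.0, 45.0, 90.0, 180.0, 225.0, 270.0)

_RESPAWN_MAX_TRIES = 10_000


class PackingError(RuntimeError):
    """Raised when dots cannot be placed without overlap inside the region."""


@dataclass(frozen=True)
class PalmRegion:
    """Square stimulation area on the palm.

    The proximal-distal extent equals the medial-lateral width (the
    motion area spans the palm from the heel of the hand to the base
    of the fingers, matched to the palm's width).
    """

    width_cm: float = 8.0
    height_cm: float = 8.0

    def __post_init__(self) -> None:
        if self.width_cm <= 0:
            raise ValueError("region width must be positive")
        if not math.isclose(self.width_cm, self.height_cm):
            raise ValueError(
                "palm motion area is square: height_cm must equal width_cm"
            )


def direction_unit_vector(direction_deg: float) -> np.ndarray:
    """Unit displacement for a direction in the palm convention (0 deg = +y)."""
    th = math.radians(direction_deg)
    return np.array([math.sin(th), math.cos(th)])


@dataclass
class StimulusSpec:
    """Parameters of one moving-dot stimulus presentation."""

    direction_deg: float
    duration_ms: float
    n_dots: int = 6
    dot_diameter_mm: float = 8.5
    speed_cm_s: float = 4.0
    frame_rate_hz: float = 100.0
    region: PalmRegion = field(default_factory=PalmRegion)
    start_points: Optional[np.ndarray] = None
    rng_seed: Optional[object] = None

    def __post_init__(self) -> None:
        if self.n_dots < 1:
            raise ValueError("n_dots must be >= 1")
        if self.speed_cm_s < 0:
            raise ValueError("speed must be non-negative")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if float(self.direction_deg) not in ALLOWED_DIRECTIONS:
            raise ValueError(
                f"direction_deg must be one of {ALLOWED_DIRECTIONS}, "
                f"got {self.direction_deg}"
            )
        if self.start_points is not None:
            pts = np.asarray(self.start_points, dtype=float)
            if pts.shape != (self.n_dots, 2):
                raise ValueError("start_points must have shape (n_dots, 2)")
            self.start_points = pts

    @property
    def dot_radius_cm(self) -> float:
        return self.dot_diameter_mm / 20.0


@dataclass(frozen=True)
class RespawnEvent:
    frame: int
    dot: int
    old_position: tuple
    new_position: tuple


@dataclass
class Trajectory:
    """Frame-by-frame dot centres plus the respawn log.

    ``frames`` has shape ``(n_frames, n_dots, 2)``; frame 0 is the
    start configuration and consecutive frames are one time step
    apart.  ``respawned[f, d]`` is True when dot ``d`` was relocated
    between frames ``f-1`` and ``f`` (its displacement at that step is
    a jump, not coherent motion).
    """

    frames: np.ndarray
    respawned: np.ndarray
    respawn_events: list
    spec: StimulusSpec

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (frame, dot)."""
        n_f, n_d, _ = self.frames.shape
        idx_f = np.repeat(np.arange(n_f), n_d)
        idx_d = np.tile(np.arange(n_d), n_f)
        flat = self.frames.reshape(-1, 2)
        return pd.DataFrame(
            {
                "frame": idx_f,
                "dot": idx_d,
                "x_cm": flat[:, 0],
                "y_cm": flat[:, 1],
                "respawned": self.respawned.reshape(-1),
            }
        )


@dataclass(frozen=True)
class MotionSummary:
    speed_cm_s: float
    direction_deg: float
    respawn_rate_hz: float
    n_respawns: int


def _inside(pts: np.ndarray, region: PalmRegion, radius: float, tol: float = 1e-9) -> np.ndarray:
    """Boolean mask: disc of each centre fully inside the region."""
    pts = np.atleast_2d(pts)
    lo = radius - tol
    return (
        (pts[:, 0] >= lo)
        & (pts[:, 0] <= region.width_cm - lo)
        & (pts[:, 1] >= lo)
        & (pts[:, 1] <= region.height_cm - lo)
    )


def _draw_position(rng: np.random.Generator, region: PalmRegion, radius: float) -> np.ndarray:
    return rng.uniform(
        [radius, radius],
        [region.width_cm - radius, region.height_cm - radius],
    )


def sample_start_points(
    n_dots: int,
    region: PalmRegion = PalmRegion(),
    dot_diameter_mm: float = 8.5,
    rng: Optional[np.random.Generator] = None,
    max_tries: int = _RESPAWN_MAX_TRIES,
) -> np.ndarray:
    """Place ``n_dots`` uniformly at random, discs inside the region, no overlap.

    Two dots overlap when their centre distance is below one dot
    diameter.  Placement is sequential rejection sampling; an
    infeasible packing raises :class:`PackingError` after
    ``max_tries`` rejected draws for a single dot.
    """
    if rng is None:
        rng = np.random.default_rng()
    radius = dot_diameter_mm / 20.0
    diameter = dot_diameter_mm / 10.0
    if region.width_cm < 2 * radius or region.height_cm < 2 * radius:
        raise PackingError("region smaller than a single dot")
    placed: list[np.ndarray] = []
    for _ in range(n_dots):
        for attempt in range(max_tries):
            cand = _draw_position(rng, region, radius)
            if all(np.linalg.norm(cand - p) >= diameter for p in placed):
                placed.append(cand)
                break
        else:
            raise PackingError(
                f"could not place {n_dots} non-overlapping dots of diameter "
                f"{diameter} cm in a {region.width_cm}x{region.height_cm} cm region "
                f"after {max_tries} tries"
            )
    return np.array(placed)


def simulate_trajectory(spec: StimulusSpec) -> Trajectory:
    """Simulate the dot field frame by frame.

    All dots share one displacement per step (coherent motion at
    ``speed_cm_s`` along ``direction_deg``).  After each step, any dot
    whose disc extends beyond the region is relocated by rejection
    sampling to a position whose disc is inside the region and whose
    centre is at least one diameter from every other dot.  Each dot
    owns an independent random sub-stream for its respawns, so one
    dot's relocations never perturb another's.

    The trajectory spans the full stimulus duration: with ``k =
    ceil(duration_ms * frame_rate / 1000)`` motion steps the result
    holds ``k + 1`` frames including the start configuration.
    """
    ss = np.random.SeedSequence(spec.rng_seed)
    children = ss.spawn(spec.n_dots + 1)
    start_rng = np.random.default_rng(children[0])
    dot_rngs = [np.random.default_rng(c) for c in children[1:]]

    radius = spec.dot_radius_cm
    diameter = 2 * radius
    if spec.start_points is not None:
        pos = np.array(spec.start_points, dtype=float)
        if not _inside(pos, spec.region, radius).all():
            raise ValueError("provided start_points extend beyond the region")
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if (d < diameter - 1e-9).any():
            raise ValueError("provided start_points overlap")
    else:
        pos = sample_start_points(
            spec.n_dots, spec.region, spec.dot_diameter_mm, rng=start_rng
        )

    n_steps = math.ceil(spec.duration_ms * spec.frame_rate_hz / 1000.0)
    dt = 1.0 / spec.frame_rate_hz
    step = direction_unit_vector(spec.direction_deg) * spec.speed_cm_s * dt

    frames = np.empty((n_steps + 1, spec.n_dots, 2))
    respawned = np.zeros((n_steps + 1, spec.n_dots), dtype=bool)
    events: list[RespawnEvent] = []
    frames[0] = pos

    cur = pos.copy()
    for f in range(1, n_steps + 1):
        cur = cur + step
        out = ~_inside(cur, spec.region, radius)
        for d_idx in np.nonzero(out)[0]:
            old = cur[d_idx].copy()
            rng_d = dot_rngs[d_idx]
            for _ in range(_RESPAWN_MAX_TRIES):
                cand = _draw_position(rng_d, spec.region, radius)
                others = np.delete(cur, d_idx, axis=0)
                if (np.linalg.norm(others - cand, axis=1) >= diameter).all():
                    break
            else:
                raise PackingError("respawn failed: no non-overlapping position found")
            cur[d_idx] = cand
            respawned[f, d_idx] = True
            events.append(RespawnEvent(f, int(d_idx), tuple(old), tuple(cand)))
        frames[f] = cur
    return Trajectory(frames=frames, respawned=respawned, respawn_events=events, spec=spec)


def summarize_motion(traj: Trajectory) -> MotionSummary:
    """Empirical speed, direction and respawn rate of a trajectory.

    Speed is the median per-step displacement (respawn steps excluded)
    times the frame rate; direction is the circular mean of the step
    displacement angles.
    """
    if traj.n_frames < 2:
        raise ValueError("speed undefined for a single-frame trajectory")
    disp = traj.frames[1:] - traj.frames[:-1]
    keep = ~traj.respawned[1:]
    vecs = disp[keep]
    norms = np.linalg.norm(vecs, axis=1)
    fr = traj.spec.frame_rate_hz
    speed = float(np.median(norms)) * fr

    moving = norms > 1e-12
    if moving.any():
        ang = np.arctan2(vecs[moving, 0], vecs[moving, 1])
        direction = math.degrees(
            math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
        ) % 360.0
    else:
        direction = float("nan")
    dur_s = (traj.n_frames - 1) / fr
    rate = len(traj.respawn_events) / (traj.spec.n_dots * dur_s)
    return MotionSummary(
        speed_cm_s=speed,
        direction_deg=direction,
        respawn_rate_hz=rate,
        n_respawns=len(traj.respawn_events),
    )
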
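"""Trial-level behavioral metrics.

Four parameters are scored from the search-phase trajectory of a trial:

* **pointing error** — absolute angular difference between the azimuth the
  navigator pointed before moving and the straight-line azimuth from the
  start to the goal center, in [0, 180] degrees; decreases with precision.
* **path efficiency** — path_min / path_real in (0, 1], where path_min is
  the straight-line distance from the start to the goal *boundary* along
  the line to the goal center, and path_real is the polyline length of the
  search-phase trajectory up to and including the first goal entry.  The
  boundary convention keeps 1.0 attainable (the search ends at the first
  boundary crossing); the ratio is capped at 1.
* **goal quadrant preference** — fraction of probe-trial samples lying in
  the 90° arena sector centered on the goal azimuth (chance = 0.25).
* **number of entrances** — count of maximal runs of consecutive in-goal
  samples during a probe trial.

Samples logged after the timeout reveal are excluded from every metric:
the parameters measure search, and the walk to a visible goal would dilute
them.  Occupancy uses equal sample weights (trajectories have constant dt
by construction; variable-dt external logs should be resampled first).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    ArenaSpec,
    GoalSpec,
    angular_difference,
    azimuth_of,
    goal_quadrant,
)

__all__ = [
    "Trajectory",
    "TrialMetrics",
    "polyline_length",
    "pointing_error",
    "path_efficiency",
    "quadrant_preference",
    "count_entrances",
    "score_trial",
    "score_session",
    "rm_block_means",
    "dmp_phase_means",
]

RM_BLOCKS = {1: (2, 3), 2: (4, 5), 3: (7, 8), 4: (9, 10)}


@dataclass
class Trajectory:
    """Time-stamped 2D path of one trial's search phase (plus post-reveal tail).

    ``t`` is strictly increasing with constant step; the first sample is at
    the start point.  ``post_reveal`` flags samples logged after the search
    time limit expired and the goal was revealed.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    start: tuple[float, float]
    pointed_azimuth: float | None = None
    post_reveal: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == n):
            raise ValueError("t, x, y must have equal length")
        if n == 0:
            raise ValueError("empty trajectory")
        if np.any(np.diff(self.t) <= 0):
            bad = int(np.argmax(np.diff(self.t) <= 0)) + 1
            raise ValueError(f"timestamps not strictly increasing at row {bad}")
        if self.post_reveal is None:
            self.post_reveal = np.zeros(n, dtype=bool)
        else:
            self.post_reveal = np.asarray(self.post_reveal, dtype=bool)
            if len(self.post_reveal) != n:
                raise ValueError("post_reveal length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def search_phase(self) -> "Trajectory":
        """The sub-trajectory before the reveal (metrics operate on this)."""
        m = ~self.post_reveal
        return Trajectory(
            self.t[m], self.x[m], self.y[m], self.start, self.pointed_azimuth
        )


@dataclass
class TrialMetrics:
    """Scored parameters of one trial; fields are None when not applicable."""

    pointing_error: float | None = None
    path_efficiency: float | None = None
    quadrant_preference: float | None = None
    entrances: int | None = None
    found: bool = False
    search_duration: float = 0.0


def polyline_length(x: np.ndarray, y: np.ndarray) -> float:
    """Total Euclidean length of the polyline through the samples."""
    return float(np.sum(np.hypot(np.diff(x), np.diff(y))))


def _in_goal_mask(traj: Trajectory, goal: GoalSpec) -> np.ndarray:
    return (
        np.hypot(traj.x - goal.center[0], traj.y - goal.center[1]) <= goal.radius
    )


def _first_entry_index(traj: Trajectory, goal: GoalSpec) -> int | None:
    search = ~traj.post_reveal
    inside = _in_goal_mask(traj, goal) & search
    idx = np.flatnonzero(inside)
    return int(idx[0]) if idx.size else None


def pointing_error(traj: Trajectory, goal: GoalSpec) -> float | None:
    """Absolute angular error of the pointed direction, degrees in [0, 180].

    Absent (None) when no pointing was recorded (first-search trials).
    """
    if traj.pointed_azimuth is None:
        return None
    true_az = azimuth_of(goal.center, traj.start)
    return angular_difference(traj.pointed_azimuth, true_az)


def path_efficiency(traj: Trajectory, goal: GoalSpec) -> float | None:
    """path_min / path_real in (0, 1]; None when the goal was not found.

    path_min runs from the start to the goal entry boundary
    (‖start − goal.center‖ − goal.radius); path_real is the search-phase
    polyline length up to and including the first in-goal sample.
    """
    i = _first_entry_index(traj, goal)
    if i is None:
        return None
    d_center = math.hypot(
        traj.start[0] - goal.center[0], traj.start[1] - goal.center[1]
    )
    path_min = d_center - goal.radius
    if path_min <= 0:
        raise ValueError("malformed trial: start point inside the goal circle")
    path_real = polyline_length(traj.x[: i + 1], traj.y[: i + 1])
    if path_real == 0:
        raise ValueError("malformed trial: zero-length path to goal entry")
    return min(path_min / path_real, 1.0)


def quadrant_preference(
    traj: Trajectory,
    goal: GoalSpec,
    arena: ArenaSpec,
    first_seconds: float | None = None,
) -> float:
    """Fraction of search-phase samples in the goal-centered quadrant.

    ``first_seconds`` restricts scoring to the initial portion of the
    trial (rodent-style early-probe scoring); by default the full trial
    is scored, matching subjects who search for the whole time limit.
    """
    if traj.duration < 1.0:
        raise ValueError("trajectory shorter than 1 s: occupancy undefined")
    sector = goal_quadrant(goal, arena)
    m = ~traj.post_reveal
    if first_seconds is not None:
        m = m & (traj.t - traj.t[0] < first_seconds)
    xs, ys = traj.x[m], traj.y[m]
    az = np.degrees(np.arctan2(ys, xs)) % 360.0
    rel = (az - (sector.center_azimuth - sector.half_width)) % 360.0
    return float(np.mean(rel < 2 * sector.half_width))


def count_entrances(traj: Trajectory, goal: GoalSpec) -> int:
    """Number of maximal runs of consecutive in-goal search-phase samples.

    An entrance is an out→in transition; a trajectory starting inside the
    goal counts its initial run as one entrance.
    """
    m = ~traj.post_reveal
    inside = _in_goal_mask(traj, goal)[m]
    if inside.size == 0:
        return 0
    starts = inside & ~np.concatenate(([False], inside[:-1]))
    return int(np.sum(starts))


def score_trial(
    traj: Trajectory | None,
    goal: GoalSpec,
    arena: ArenaSpec,
    is_probe: bool = False,
) -> TrialMetrics:
    """Score one trial. Probe trials get occupancy metrics, others path metrics."""
    if traj is None:
        return TrialMetrics()
    i = _first_entry_index(traj, goal)
    found = i is not None
    search = traj.t[~traj.post_reveal]
    out = TrialMetrics(
        pointing_error=pointing_error(traj, goal),
        found=bool(found) and not is_probe,
        search_duration=float(
            traj.t[i] - traj.t[0] if (found and not is_probe) else search[-1] - search[0]
        ),
    )
    if is_probe:
        out.quadrant_preference = quadrant_preference(traj, goal, arena)
        out.entrances = count_entrances(traj, goal)
    elif found:
        out.path_efficiency = path_efficiency(traj, goal)
    return out


def score_session(session, trajectories) -> pd.DataFrame:
    """Score every trial of a session against its trajectory.

    ``trajectories`` is a sequence aligned with ``session.trials``; a None
    entry yields a row of absent metrics flagged ``missing``.  Returns a
    tidy frame, one row per trial.
    """
    if len(trajectories) != len(session.trials):
        raise ValueError(
            f"{len(trajectories)} trajectories for {len(session.trials)} trials"
        )
    rows = []
    for trial, traj in zip(session.trials, trajectories):
        is_probe = not trial.goal.active
        m = score_trial(traj, trial.goal, session.arena, is_probe=is_probe)
        rows.append(
            {
                "trial": trial.index,
                "phase": trial.phase_label,
                "goal_id": trial.goal_id,
                "pointing_error": m.pointing_error,
                "path_efficiency": m.path_efficiency,
                "quadrant_preference": m.quadrant_preference,
                "entrances": m.entrances,
                "found": m.found,
                "search_duration": m.search_duration,
                "missing": traj is None,
            }
        )
    df = pd.DataFrame(rows)
    for col in (
        "pointing_error",
        "path_efficiency",
        "quadrant_preference",
        "entrances",
        "search_duration",
    ):
        df[col] = pd.to_numeric(df[col])
    return df


def rm_block_means(trial_df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a reference-memory session into its four standard-trial blocks.

    Blocks are the trial pairs (T2,T3), (T4,T5), (T7,T8), (T9,T10); the
    probe (T6), the first search (T1) and the visible-goal control (T11)
    do not enter any block.
    """
    rows = []
    for block, pair in RM_BLOCKS.items():
        sub = trial_df[trial_df["trial"].isin(pair)]
        rows.append(
            {
                "block": block,
                "pointing_error": sub["pointing_error"].mean(),
                "path_efficiency": sub["path_efficiency"].mean(),
            }
        )
    return pd.DataFrame(rows)


def dmp_phase_means(trial_df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a delayed-matching-to-place session by phase.

    Returns one row per (phase_unit, goal): acquisition repetitions 1–3 per
    goal, recall rounds 1–2 per goal, probe per goal.
    """
    rows = []
    acq = trial_df[trial_df["phase"] == "DMP_acq"]
    for gid in ("A", "B", "C"):
        sub = acq[acq["goal_id"] == gid].sort_values("trial")
        for rep, (_, r) in enumerate(sub.iterrows(), start=1):
            rows.append(
                {
                    "phase": "acq",
                    "unit": rep,
                    "goal_id": gid,
                    "pointing_error": r["pointing_error"],
                    "path_efficiency": r["path_efficiency"],
                    "quadrant_preference": r["quadrant_preference"],
                    "entrances": r["entrances"],
                }
            )
    rec = trial_df[trial_df["phase"] == "DMP_recall"].sort_values("trial")
    for rnd in (1, 2):
        chunk = rec.iloc[(rnd - 1) * 3 : rnd * 3]
        for _, r in chunk.iterrows():
            rows.append(
                {
                    "phase": "recall",
                    "unit": rnd,
                    "goal_id": r["goal_id"],
                    "pointing_error": r["pointing_error"],
                    "path_efficiency": r["path_efficiency"],
                    "quadrant_preference": r["quadrant_preference"],
                    "entrances": r["entrances"],
                }
            )
    probe = trial_df[trial_df["phase"] == "DMP_probe"]
    for _, r in probe.iterrows():
        rows.append(
            {
                "phase": "probe",
                "unit": 1,
                "goal_id": r["goal_id"],
                "pointing_error": r["pointing_error"],
                "path_efficiency": r["path_efficiency"],
                "quadrant_preference": r["quadrant_preference"],
                "entrances": r["entrances"],
            }
        )
    return pd.DataFrame(rows)
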
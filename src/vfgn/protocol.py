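"""Trial state machine and session schedules.

Two session types are encoded:

* **Reference memory (RM)** — 11 trials with a stable hidden goal: a first
  free-search trial (T1, no pointing), four blocks of two standard trials
  (T2–T5 and T7–T10), a probe trial with the goal inactivated in the middle
  (T6), and a visible-goal visuo-motor control trial at the end (T11).
* **Delayed matching to place (DMP)** — 18 trials over three goal positions
  A, B, C: an acquisition phase of 3 consecutive trials per goal (the first
  trial of each goal is an announced positional change, no pointing), a
  recall phase of two rounds of the sequence A, B, C, and a probe phase of
  one round A, B, C with the goals inactivated.

Each trial runs as: the navigator stands at the start point, points toward
the believed goal azimuth (except first-search trials), then moves under a
simple kinematic model (constant translation speed, bounded turn rate)
until it enters an active goal or the search time limit expires.  On
timeout the goal is revealed and the walk to it is logged flagged
``post_reveal`` (and excluded from metrics downstream).  Probe trials
always run the full time limit.  The 10 s memorize phase is represented
only as a learning event delivered to the agent, not as logged motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ArenaSpec, CueSet, GoalSpec, angular_difference, azimuth_of, in_goal
from .metrics import Trajectory

__all__ = [
    "Kinematics",
    "TrialSpec",
    "SessionSpec",
    "TrialPhaseTrace",
    "sample_start",
    "build_rm_session",
    "build_dmp_session",
    "run_trial",
    "run_session",
]

RM_PHASES = ("RM_search", "RM_standard", "RM_probe", "RM_visible")
DMP_PHASES = ("DMP_acq", "DMP_recall", "DMP_probe")

#: Default kinematics: 7 m/s translation crosses the default arena in ~8 s,
#: leaving headroom within the 60 s limit; turn rate bounded at 90°/s.
START_RADIUS_FRAC = 0.92
START_GRID_DEG = 45.0
POST_REVEAL_CAP = 30.0  # extra seconds allowed for the walk to a revealed goal


@dataclass(frozen=True)
class Kinematics:
    speed: float = 7.0          # m/s
    max_turn_rate: float = 90.0  # deg/s
    dt: float = 0.1             # s

    def __post_init__(self):
        if self.speed <= 0 or self.dt <= 0 or self.max_turn_rate <= 0:
            raise ValueError("kinematic parameters must be positive")


@dataclass(frozen=True)
class TrialSpec:
    index: int                      # 1-based ordinal within the session
    phase_label: str
    goal_id: str                    # "RM", "A", "B" or "C"
    goal: GoalSpec
    start: tuple[float, float]
    search_limit: float = 60.0
    memorize_time: float = 10.0
    pointing_required: bool = True

    def __post_init__(self):
        if self.phase_label not in RM_PHASES + DMP_PHASES:
            raise ValueError(f"unknown phase label {self.phase_label!r}")
        if self.search_limit <= 0:
            raise ValueError("search_limit must be positive")
        if self.phase_label in ("RM_probe", "DMP_probe") and self.goal.active:
            raise ValueError("probe trials require an inactivated goal")
        if self.phase_label == "RM_visible" and not self.goal.visible:
            raise ValueError("visible-goal control trial requires goal.visible")


@dataclass(frozen=True)
class SessionSpec:
    trials: tuple[TrialSpec, ...]
    cue_set: CueSet
    goal_positions: dict
    rng_seed: int
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    kinematics: Kinematics = field(default_factory=Kinematics)


@dataclass
class TrialPhaseTrace:
    """Timestamps of one trial's phases (seconds from movement activation)."""

    pointing_time: float | None = None
    search_start: float = 0.0
    goal_entry_time: float | None = None
    timeout: bool = False
    reveal: bool = False

    def __post_init__(self):
        if self.goal_entry_time is not None and self.goal_entry_time < self.search_start:
            raise ValueError("goal entry precedes search start")


def _start_point(arena: ArenaSpec, azimuth: float) -> tuple[float, float]:
    r = START_RADIUS_FRAC * arena.radius
    return (r * math.cos(math.radians(azimuth)), r * math.sin(math.radians(azimuth)))


def sample_start(
    arena: ArenaSpec,
    goal: GoalSpec,
    previous_start: tuple[float, float] | None,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Draw a pseudorandom start near the wall.

    Starts sit on the circle of radius 0.92·R at one of 8 azimuths on a 45°
    grid, excluding azimuths within 45° of the goal azimuth (so the goal is
    never trivially close) and excluding the previous start.  At least four
    candidates always remain.
    """
    goal_az = azimuth_of(goal.center)
    prev_az = None if previous_start is None else azimuth_of(previous_start)
    candidates = []
    for k in range(8):
        az = k * START_GRID_DEG
        if angular_difference(az, goal_az) <= 45.0:
            continue
        if prev_az is not None and angular_difference(az, prev_az) < 1e-9:
            continue
        candidates.append(az)
    az = candidates[rng.integers(len(candidates))]
    return _start_point(arena, az)


def _validate_goal(arena: ArenaSpec, center, radius: float) -> None:
    goal = GoalSpec(tuple(center), radius)
    goal.validate_inside(arena)
    if math.hypot(*goal.center) == 0.0:
        raise ValueError("goal at arena center: quadrant/azimuth undefined downstream")


def build_rm_session(
    arena: ArenaSpec,
    cue_set: CueSet,
    goal_pos: tuple[float, float],
    seed: int,
    goal_radius: float = 2.8,
) -> SessionSpec:
    """Build the 11-trial reference-memory schedule.

    T1 first search (no pointing), T2–T5 standard, T6 probe (goal
    inactivated), T7–T10 standard, T11 visible-goal control.  The goal
    position is stable throughout; start positions are drawn by
    :func:`sample_start` deterministically from ``seed``.
    """
    _validate_goal(arena, goal_pos, goal_radius)
    cue_set.validate(arena)
    rng = np.random.default_rng(seed)
    base = GoalSpec(tuple(goal_pos), goal_radius)
    trials = []
    prev = None
    for i in range(1, 12):
        if i == 1:
            phase, goal, pointing = "RM_search", base, False
        elif i == 6:
            phase, goal, pointing = "RM_probe", replace(base, active=False), True
        elif i == 11:
            phase, goal, pointing = "RM_visible", replace(base, visible=True), True
        else:
            phase, goal, pointing = "RM_standard", base, True
        start = sample_start(arena, base, prev, rng)
        prev = start
        trials.append(
            TrialSpec(i, phase, "RM", goal, start, pointing_required=pointing)
        )
    return SessionSpec(
        tuple(trials), cue_set, {"RM": tuple(goal_pos)}, seed, arena
    )


def build_dmp_session(
    arena: ArenaSpec,
    cue_set: CueSet,
    goal_positions: dict,
    seed: int,
    goal_radius: float = 2.8,
) -> SessionSpec:
    """Build the 18-trial delayed-matching-to-place schedule.

    Acquisition A1 A2 A3 B1 B2 B3 C1 C2 C3 (A1/B1/C1 are announced
    positional changes, no pointing), recall A B C A B C, probe A B C with
    inactivated goals.
    """
    if sorted(goal_positions) != ["A", "B", "C"]:
        raise ValueError("goal_positions must map exactly the ids A, B, C")
    for gid, pos in goal_positions.items():
        _validate_goal(arena, pos, goal_radius)
    ids = ("A", "B", "C")
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            pa, pb = goal_positions[a], goal_positions[b]
            if math.hypot(pa[0] - pb[0], pa[1] - pb[1]) <= 2 * goal_radius:
                raise ValueError(f"goal circles {a} and {b} overlap")
    cue_set.validate(arena)
    rng = np.random.default_rng(seed)
    goals = {g: GoalSpec(tuple(goal_positions[g]), goal_radius) for g in ids}
    trials = []
    prev = None
    idx = 1

    def add(gid, phase, pointing, goal):
        nonlocal prev, idx
        start = sample_start(arena, goals[gid], prev, rng)
        prev = start
        trials.append(TrialSpec(idx, phase, gid, goal, start, pointing_required=pointing))
        idx += 1

    for gid in ids:                      # acquisition: 3 consecutive per goal
        for rep in range(3):
            add(gid, "DMP_acq", rep > 0, goals[gid])
    for _ in range(2):                   # recall: two rounds of A, B, C
        for gid in ids:
            add(gid, "DMP_recall", True, goals[gid])
    for gid in ids:                      # probe: one round, goals inactivated
        add(gid, "DMP_probe", True, replace(goals[gid], active=False))
    return SessionSpec(
        tuple(trials),
        cue_set,
        {g: tuple(goal_positions[g]) for g in ids},
        seed,
        arena,
    )


def run_trial(
    trial: TrialSpec,
    policy,
    dt: float | None = None,
    kinematics: Kinematics | None = None,
    arena: ArenaSpec | None = None,
) -> tuple[Trajectory, TrialPhaseTrace]:
    """Simulate one trial under an agent policy.

    The policy contract: ``begin_trial(trial)`` before pointing;
    ``point(trial) -> azimuth`` (called only when pointing is required);
    ``desired_heading(x, y, heading, t) -> azimuth or None`` per step
    (None = stand still); ``end_trial(trial, entered_goal)`` after the run
    (an ``entered_goal`` of True is the learning event: the navigator stood
    on the goal, including after a timeout reveal).

    Search-phase positions are logged at fixed dt from movement activation
    until first goal entry (active goals) or until the time limit; after a
    timeout the goal is revealed and the simulator steers the navigator
    straight to it, logging the tail flagged ``post_reveal``.  Probe trials
    always run the full time limit and end without reveal or learning
    event.  Positions are clipped to the arena wall.
    """
    kin = kinematics or Kinematics()
    if dt is not None:
        kin = replace(kin, dt=dt)
    arena = arena or ArenaSpec()
    h = kin.dt
    probe = not trial.goal.active

    policy.begin_trial(trial)
    pointed = policy.point(trial) if trial.pointing_required else None

    x, y = trial.start
    heading = azimuth_of((0.0, 0.0), trial.start)  # face the arena center
    max_turn = kin.max_turn_rate * h
    step_len = kin.speed * h

    ts, xs, ys, pr = [0.0], [x], [y], [False]
    t = 0.0
    revealed = False
    entry_time: float | None = None
    goal = trial.goal
    hard_cap = trial.search_limit + POST_REVEAL_CAP

    while True:
        if not probe and in_goal((x, y), goal):
            entry_time = t
            break
        if t >= trial.search_limit:
            if probe:
                break
            revealed = True
        if t >= hard_cap:
            break
        if revealed:
            desired = azimuth_of(goal.center, (x, y))
        else:
            desired = policy.desired_heading(x, y, heading, t)
        if desired is not None:
            turn = ((desired - heading + 180.0) % 360.0) - 180.0
            turn = max(-max_turn, min(max_turn, turn))
            heading = (heading + turn) % 360.0
            x += step_len * math.cos(math.radians(heading))
            y += step_len * math.sin(math.radians(heading))
            if x * x + y * y > arena.radius * arena.radius:
                x, y = arena.clip((x, y))
        t += h
        ts.append(t)
        xs.append(x)
        ys.append(y)
        pr.append(revealed)

    traj = Trajectory(
        np.array(ts), np.array(xs), np.array(ys), trial.start, pointed, np.array(pr)
    )
    entered = entry_time is not None and not probe
    policy.end_trial(trial, entered)
    trace = TrialPhaseTrace(
        pointing_time=0.0 if trial.pointing_required else None,
        search_start=0.0,
        goal_entry_time=entry_time,
        timeout=revealed or (probe and entry_time is None),
        reveal=revealed,
    )
    return traj, trace


def run_session(session: SessionSpec, policy, dt: float | None = None):
    """Run every trial of a session in order; returns (trajectories, traces)."""
    trajs, traces = [], []
    for trial in session.trials:
        traj, trace = run_trial(
            trial, policy, dt=dt, kinematics=session.kinematics, arena=session.arena
        )
        trajs.append(traj)
        traces.append(trace)
    return trajs, traces
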
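"""End-to-end cohort pipelines: simulate → score → tabulate.

These helpers bind the protocol, agents and metrics modules into the
tables the analysis stage consumes, and host the two simulation studies
that have closed-form expectations: the chance-level occupancy of a
goal-naive explorer (25% by symmetry) and the null calibration of the
mixed ANOVA group test (rejection rate ≈ α under identical group presets).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .agents import (
    AgentParams,
    MemoryNavigator,
    RandomExplorer,
    Subject,
    load_preset,
    make_cohort,
    rm_pointing_trials,
)
from .analysis import mixed_anova
from .geometry import ArenaSpec, CueSet, GoalSpec
from .metrics import dmp_phase_means, rm_block_means, score_session
from .protocol import TrialSpec, build_dmp_session, build_rm_session, run_session, run_trial

__all__ = [
    "default_rm_goal",
    "default_dmp_goals",
    "simulate_subject_session",
    "simulate_rm_cohort",
    "simulate_dmp_cohort",
    "dmp_recall_drop_table",
    "chance_quadrant_preference",
    "null_calibration",
]

_GOAL_RADIAL = 14.0  # m from center: mid-radius, geometrically equivalent slots


def _polar(r: float, az_deg: float) -> tuple[float, float]:
    return (r * math.cos(math.radians(az_deg)), r * math.sin(math.radians(az_deg)))


def default_rm_goal() -> tuple[float, float]:
    """Stable reference-memory goal: mid-radius at azimuth 45°."""
    return _polar(_GOAL_RADIAL, 45.0)


def default_dmp_goals() -> dict:
    """Three goal slots 120° apart, each in the same relation to its nearest cue."""
    return {
        "A": _polar(_GOAL_RADIAL, 45.0),
        "B": _polar(_GOAL_RADIAL, 165.0),
        "C": _polar(_GOAL_RADIAL, 285.0),
    }


def simulate_subject_session(subject: Subject, session, seed: int) -> pd.DataFrame:
    """Run one subject through a session and score it (per-trial rows)."""
    rng = np.random.default_rng(seed)
    policy = MemoryNavigator(subject.params, session.arena, rng)
    trajs, _ = run_session(session, policy)
    df = score_session(session, trajs)
    df.insert(0, "subject", subject.subject_id)
    df.insert(1, "group", subject.group)
    df.insert(2, "sex", subject.sex)
    df.insert(3, "age", subject.age)
    return df


def _cohort_tables(cohort, build, aggregate, seed):
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(2 * len(cohort))
    trial_frames, agg_frames = [], []
    for i, subj in enumerate(cohort):
        session_seed = int(child[2 * i].generate_state(1)[0] % (2**31))
        agent_seed = int(child[2 * i + 1].generate_state(1)[0] % (2**31))
        session = build(session_seed)
        tdf = simulate_subject_session(subj, session, agent_seed)
        adf = aggregate(tdf)
        for col, val in (
            ("age", subj.age),
            ("sex", subj.sex),
            ("group", subj.group),
            ("subject", subj.subject_id),
        ):
            adf.insert(0, col, val)
        trial_frames.append(tdf)
        agg_frames.append(adf)
    return (
        pd.concat(trial_frames, ignore_index=True),
        pd.concat(agg_frames, ignore_index=True),
    )


def simulate_rm_cohort(
    cohort: list[Subject],
    seed: int,
    arena: ArenaSpec | None = None,
    goal_pos: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a reference-memory session per subject.

    Returns (trial table, block table): the block table holds the four
    standard-trial block means per subject — the repeated-measures input
    for the mixed ANOVA.
    """
    arena = arena or ArenaSpec()
    goal_pos = goal_pos or default_rm_goal()
    cues = CueSet.default(arena, "rm")

    def build(s):
        return build_rm_session(arena, cues, goal_pos, s)

    return _cohort_tables(cohort, build, rm_block_means, seed)


def simulate_dmp_cohort(
    cohort: list[Subject],
    seed: int,
    arena: ArenaSpec | None = None,
    goal_positions: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a delayed-matching-to-place session per subject.

    Returns (trial table, phase table): the phase table has one row per
    (phase, unit, goal) — acquisition repetition, recall round, probe.
    """
    arena = arena or ArenaSpec()
    goal_positions = goal_positions or default_dmp_goals()
    cues = CueSet.default(arena, "dmp")

    def build(s):
        return build_dmp_session(arena, cues, goal_positions, s)

    return _cohort_tables(cohort, build, dmp_phase_means, seed)


def dmp_recall_drop_table(phase_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean pointing error at the end of acquisition vs recall.

    One row per subject with columns ``acq3`` (mean over the third
    acquisition trial of each goal), ``recall1`` and ``recall2`` (mean per
    recall round); the acq3→recall1 difference is the delay-induced
    performance drop.
    """
    rows = []
    for (sid, grp), sub in phase_table.groupby(["subject", "group"]):
        acq3 = sub[(sub["phase"] == "acq") & (sub["unit"] == 3)]["pointing_error"].mean()
        r1 = sub[(sub["phase"] == "recall") & (sub["unit"] == 1)]["pointing_error"].mean()
        r2 = sub[(sub["phase"] == "recall") & (sub["unit"] == 2)]["pointing_error"].mean()
        rows.append(
            {"subject": sid, "group": grp, "acq3": acq3, "recall1": r1, "recall2": r2}
        )
    return pd.DataFrame(rows)


def chance_quadrant_preference(
    n_trials: int = 1000,
    seed: int = 0,
    trial_seconds: float = 60.0,
    arena: ArenaSpec | None = None,
) -> tuple[float, float, int]:
    """Mean goal-quadrant occupancy of a goal-naive random explorer.

    Runs ``n_trials`` full-length probe trials of a correlated random walk
    that uses no goal information, starting at a uniformly random azimuth
    on the start circle.  With a goal-independent start the walk is
    rotationally exchangeable with respect to the goal sector, so the
    expected occupancy of the 90° goal quadrant is exactly 0.25 (the
    protocol's own start sampler is goal-*dependent* — it excludes starts
    near the goal — and is deliberately not used for this baseline).

    Returns (mean preference, Monte-Carlo standard error of the mean, n).
    """
    from .metrics import quadrant_preference

    arena = arena or ArenaSpec()
    goal = GoalSpec(default_rm_goal(), active=False)
    rng = np.random.default_rng(seed)
    policy = RandomExplorer(rng, arena=arena)
    prefs = np.empty(n_trials)
    r0 = 0.92 * arena.radius
    for i in range(n_trials):
        az = rng.uniform(0.0, 360.0)
        start = (r0 * math.cos(math.radians(az)), r0 * math.sin(math.radians(az)))
        trial = TrialSpec(
            1, "RM_probe", "RM", goal, start,
            search_limit=trial_seconds, pointing_required=False,
        )
        traj, _ = run_trial(trial, policy, arena=arena)
        prefs[i] = quadrant_preference(traj, goal, arena)
    return float(prefs.mean()), float(prefs.std(ddof=1) / math.sqrt(n_trials)), n_trials


def null_calibration(
    n_reps: int = 1000,
    n_per_group: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    preset: str | dict = "healthy_like",
) -> float:
    """Rejection rate of the ANOVA group effect under identical group presets.

    Both groups draw subjects from the same preset; per replicate a cohort
    of 2 × ``n_per_group`` agents generates reference-memory pointing-error
    block means (4 blocks) through the navigator's kinematics-free pointing
    channel, and the mixed ANOVA group effect is tested at ``alpha``.  A
    calibrated test rejects in ≈ alpha of replicates.
    """
    if isinstance(preset, str):
        preset = load_preset(preset)
    from .metrics import RM_BLOCKS

    root = np.random.SeedSequence(seed)
    goal = default_rm_goal()
    arena = ArenaSpec()
    rejections = 0
    for rep, child in enumerate(root.spawn(n_reps)):
        rng = np.random.default_rng(child)
        cohort_seed = int(rng.integers(2**31))
        cohort = make_cohort({"g1": preset, "g2": preset}, n_per_group, cohort_seed)
        rows = []
        for subj in cohort:
            pe = rm_pointing_trials(subj.params, goal, rng, arena)
            for block, pair in RM_BLOCKS.items():
                rows.append(
                    {
                        "subject": subj.subject_id,
                        "group": subj.group,
                        "block": block,
                        "pointing_error": np.mean([pe[j] for j in pair]),
                    }
                )
        table = pd.DataFrame(rows)
        res = mixed_anova(table, "pointing_error")
        if res.p("group") < alpha:
            rejections += 1
    return rejections / n_reps
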
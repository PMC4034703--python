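"""Synthetic navigator policies.

These agents generate trajectories with the statistical structure the task
assumes of human subjects: pointing and path directness improve with
repeated exposure to a goal, degrade with memory noise and with intervening
trials, and fall to chance for naive exploration.  No claim of cognitive
realism is made; the generative model is deliberately simple and isolated
behind the policy interface.

The memory model: after ``n`` observations of a goal (a trial ending on
it), the per-trial estimate of its position is the true position plus
isotropic Gaussian noise with

    sigma_t = memory_sd0 * memory_decay**(n - 1) + forget_sd * staleness

where ``staleness`` counts intervening trials of a *different* goal since
the last observation.  Learning rides on observation count, not elapsed
time: recall-phase degradation is produced entirely by the staleness term.
With probability ``lapse_rate`` a trial is a pure-exploration lapse.  The
pointed direction is the azimuth of the per-trial estimate plus Gaussian
noise of SD ``pointing_sd``.  A navigator that reaches its estimate
without finding the goal performs an outward Archimedean spiral (pitch =
goal radius) around it, returning to the estimate when the spiral grows
past a belief-scaled radius — a persistent local search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources

import numpy as np
import yaml

from .geometry import ArenaSpec, GoalSpec, azimuth_of
from .protocol import Kinematics, TrialSpec, sample_start

__all__ = [
    "AgentParams",
    "MemoryStore",
    "RandomExplorer",
    "MemoryNavigator",
    "random_explorer",
    "memory_navigator",
    "Subject",
    "make_cohort",
    "load_preset",
    "list_presets",
    "rm_pointing_trials",
]


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the memory navigator (angles in degrees, lengths in m)."""

    pointing_sd: float = 8.0     # angular noise on the pointed direction
    memory_sd0: float = 12.0     # estimate spread after one observation
    memory_decay: float = 0.75   # multiplicative shrink per extra observation
    forget_sd: float = 0.2       # spread added per intervening other-goal trial
    heading_sd: float = 6.0      # random-walk heading noise, deg per step
    lapse_rate: float = 0.02     # probability of a pure-exploration trial
    seed: int | None = None

    def __post_init__(self):
        for name in ("pointing_sd", "memory_sd0", "forget_sd", "heading_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.memory_decay <= 1.0):
            raise ValueError("memory_decay must be in (0, 1]")
        if not (0.0 <= self.lapse_rate <= 1.0):
            raise ValueError("lapse_rate must be in [0, 1]")


@dataclass
class _GoalMemory:
    estimate: tuple[float, float]
    n_obs: int = 1
    staleness: int = 0


class MemoryStore(dict):
    """Per-goal memory: goal_id -> (estimate, observation count, staleness)."""

    def observe(self, goal_id: str, position: tuple[float, float]) -> None:
        if goal_id in self:
            m = self[goal_id]
            m.estimate = position
            m.n_obs += 1
            m.staleness = 0
        else:
            self[goal_id] = _GoalMemory(position)

    def age_others(self, goal_id: str) -> None:
        for gid, m in self.items():
            if gid != goal_id:
                m.staleness += 1

    def sigma(self, goal_id: str, params: AgentParams) -> float:
        m = self[goal_id]
        return (
            params.memory_sd0 * params.memory_decay ** (m.n_obs - 1)
            + params.forget_sd * m.staleness
        )


class RandomExplorer:
    """Goal-naive correlated random walk, reflected at the wall.

    Heading is perturbed by Gaussian noise at each step; near the wall an
    outward heading is reflected about the local tangent.  Pointing is
    uniformly random.  Uses no goal information.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        heading_sd: float = 6.0,
        arena: ArenaSpec | None = None,
    ):
        self.rng = rng
        self.heading_sd = heading_sd
        self.arena = arena or ArenaSpec()

    def begin_trial(self, trial: TrialSpec) -> None:
        pass

    def point(self, trial: TrialSpec) -> float:
        return float(self.rng.uniform(0.0, 360.0))

    def desired_heading(self, x: float, y: float, heading: float, t: float):
        r = math.hypot(x, y)
        if r > 0.9 * self.arena.radius:
            out_az = math.degrees(math.atan2(y, x))
            # reflect about the wall tangent when heading outward
            if math.cos(math.radians(heading - out_az)) > 0.0:
                return (2.0 * out_az + 180.0 - heading) % 360.0
        return (heading + self.rng.normal(0.0, self.heading_sd)) % 360.0

    def end_trial(self, trial: TrialSpec, entered_goal: bool) -> None:
        pass


class MemoryNavigator:
    """Navigator that points and navigates from a noisy goal memory.

    Behavior per trial: lapse trials (probability ``lapse_rate``) and
    trials for a never-observed goal fall back to random exploration.
    Otherwise the agent draws a per-trial estimate of the goal position,
    points at its azimuth (plus pointing noise), walks straight to it, and
    spirals outward around it until the goal is entered or time runs out.
    Visible-goal control trials steer at the true goal directly.  Every
    trial that ends standing on the goal (including after a timeout
    reveal) delivers a true observation.
    """

    REACH_TOL = 1.0  # m: distance at which the estimate counts as reached

    def __init__(
        self,
        params: AgentParams,
        arena: ArenaSpec | None = None,
        rng: np.random.Generator | None = None,
    ):
        self.params = params
        self.arena = arena or ArenaSpec()
        self.rng = rng if rng is not None else np.random.default_rng(params.seed)
        self.memory = MemoryStore()
        self._explorer = RandomExplorer(self.rng, params.heading_sd, self.arena)
        self._mode = "explore"
        self._target: tuple[float, float] | None = None

    # -- trial lifecycle -------------------------------------------------
    def begin_trial(self, trial: TrialSpec) -> None:
        self._trial = trial
        self._spiraling = False
        p = self.params
        if trial.goal.visible:
            self._mode = "visible"
            self._target = trial.goal.center
            return
        if trial.goal_id not in self.memory:
            self._mode = "explore"
            return
        if self.rng.random() < p.lapse_rate:
            self._mode = "explore"
            return
        self._mode = "navigate"
        sigma = self.memory.sigma(trial.goal_id, p)
        est = self.memory[trial.goal_id].estimate
        tx = est[0] + self.rng.normal(0.0, sigma)
        ty = est[1] + self.rng.normal(0.0, sigma)
        self._target = self.arena.clip((tx, ty))
        # persistent local search: spiral out to a belief-scaled radius
        gr = trial.goal.radius
        self._spiral_rmax = 2.0 * gr + min(2.0 * sigma, 1.5 * gr)
        self._spiral_b = gr / (2.0 * math.pi)

    def point(self, trial: TrialSpec) -> float:
        if self._mode == "explore":
            return float(self.rng.uniform(0.0, 360.0))
        az = azimuth_of(self._target, trial.start)
        return (az + self.rng.normal(0.0, self.params.pointing_sd)) % 360.0

    def desired_heading(self, x: float, y: float, heading: float, t: float):
        if self._mode == "explore":
            return self._explorer.desired_heading(x, y, heading, t)
        tx, ty = self._target
        d = math.hypot(x - tx, y - ty)
        if self._mode == "visible":
            return azimuth_of(self._target, (x, y))
        if not self._spiraling:
            if d > self.REACH_TOL:
                return azimuth_of(self._target, (x, y))
            self._spiraling = True
            self._phi = math.radians(azimuth_of((x, y), self._target))
            self._r = max(d, 0.5)
        # advance the Archimedean spiral by one step's arc length
        b = self._spiral_b
        speed_step = 0.7  # m advanced along the spiral per call (speed*dt)
        self._phi += speed_step / max(self._r, b)
        self._r += b * speed_step / max(self._r, b)
        if self._r > self._spiral_rmax:
            self._spiraling = False  # return to the estimate and respiral
            return azimuth_of(self._target, (x, y))
        nx = tx + self._r * math.cos(self._phi)
        ny = ty + self._r * math.sin(self._phi)
        return azimuth_of((nx, ny), (x, y))

    def end_trial(self, trial: TrialSpec, entered_goal: bool) -> None:
        if entered_goal:
            self.memory.observe(trial.goal_id, trial.goal.center)
        self.memory.age_others(trial.goal_id)


def random_explorer(rng: np.random.Generator, **kw) -> RandomExplorer:
    """Factory for the goal-naive exploration policy."""
    return RandomExplorer(rng, **kw)


def memory_navigator(params: AgentParams, **kw) -> MemoryNavigator:
    """Factory for the memory-based navigation policy."""
    return MemoryNavigator(params, **kw)


# ---------------------------------------------------------------------------
# cohorts and presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Subject:
    subject_id: str
    group: str
    sex: str
    age: float
    params: AgentParams


_PARAM_BOUNDS = {
    "pointing_sd": (0.5, 90.0),
    "memory_sd0": (0.1, 25.0),
    "memory_decay": (0.05, 1.0),
    "forget_sd": (0.0, 10.0),
    "heading_sd": (0.5, 45.0),
    "lapse_rate": (0.0, 0.9),
}


def load_preset(name: str) -> dict:
    """Load a shipped agent preset (``healthy_like`` or ``impaired_like``)."""
    ref = resources.files("vfgn.presets").joinpath(f"{name}.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def list_presets() -> list[str]:
    return sorted(
        p.name[:-5]
        for p in resources.files("vfgn.presets").iterdir()
        if p.name.endswith(".yaml")
    )


def _draw_params(preset: dict, rng: np.random.Generator, age: float) -> AgentParams:
    means = dict(preset["params"])
    sds = preset.get("between_sd", {})
    drawn = {}
    for name, (lo, hi) in _PARAM_BOUNDS.items():
        v = means.get(name, getattr(AgentParams, name))
        v = v + rng.normal(0.0, sds.get(name, 0.0)) if sds.get(name, 0.0) > 0 else v
        drawn[name] = float(min(max(v, lo), hi))
    slope = preset.get("age_slope_memory_sd0", 0.0)
    if slope:
        lo, hi = _PARAM_BOUNDS["memory_sd0"]
        drawn["memory_sd0"] = float(
            min(max(drawn["memory_sd0"] + slope * (age - 27.0), lo), hi)
        )
    return AgentParams(**drawn)


def make_cohort(
    group_presets: dict[str, dict | str],
    n_per_group: int,
    seed: int,
) -> list[Subject]:
    """Draw a cohort of agents with per-subject parameters.

    ``group_presets`` maps a group label to a preset dict (or a shipped
    preset name); per-subject parameters are the preset means plus
    between-subject Gaussian spread (``between_sd``), clipped to valid
    ranges.  Ages are uniform on [18, 35] (the recruitment band of a
    typical first-episode cohort); sex alternates to a near-balanced
    split.  Reproducible given ``seed``; the drawn parameters are carried
    on each :class:`Subject` as ground truth for recovery tests.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    cohort = []
    for group in sorted(group_presets):
        preset = group_presets[group]
        if isinstance(preset, str):
            preset = load_preset(preset)
        for i in range(n_per_group):
            age = float(rng.uniform(18.0, 35.0))
            sex = "M" if rng.random() < 0.5 else "F"
            params = _draw_params(preset, rng, age)
            cohort.append(
                Subject(f"{group}-{i + 1:03d}", group, sex, age, params)
            )
    return cohort


# ---------------------------------------------------------------------------
# kinematics-free pointing channel
# ---------------------------------------------------------------------------

def rm_pointing_trials(
    params: AgentParams,
    goal_pos: tuple[float, float],
    rng: np.random.Generator,
    arena: ArenaSpec | None = None,
) -> dict[int, float]:
    """Pointing errors of the RM standard trials T2–T5, T7–T10, without kinematics.

    In the full model the pointing error of a trial depends only on the
    per-trial goal estimate, the start point and the pointing noise — not
    on the trajectory — provided every preceding trial ended on the goal
    (guaranteed in RM sessions by the timeout reveal).  This closed-form
    channel reproduces that distribution exactly and is used where full
    kinematics would be wasteful (large replicate counts).  The probe T6
    contributes no pointing to block scores and does not reset staleness;
    with a single goal the staleness term stays zero throughout.
    """
    arena = arena or ArenaSpec()
    goal = GoalSpec(tuple(goal_pos))
    out = {}
    prev = None
    n_obs = 0
    for trial_idx in range(1, 11):
        start = sample_start(arena, goal, prev, rng)
        prev = start
        if trial_idx == 1:
            n_obs = 1  # first search ends on the goal (found or revealed)
            continue
        if trial_idx == 6:
            continue  # probe: pointing recorded but not block-scored
        true_az = azimuth_of(goal.center, start)
        if rng.random() < params.lapse_rate:
            pointed = rng.uniform(0.0, 360.0)
        else:
            sigma = params.memory_sd0 * params.memory_decay ** (n_obs - 1)
            ex = goal.center[0] + rng.normal(0.0, sigma)
            ey = goal.center[1] + rng.normal(0.0, sigma)
            pointed = azimuth_of((ex, ey), start) + rng.normal(0.0, params.pointing_sd)
        d = abs(pointed - true_az) % 360.0
        out[trial_idx] = min(d, 360.0 - d)
        n_obs += 1
    return out
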
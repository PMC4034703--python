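import math

import numpy as np
import pytest

from vfgn.geometry import ArenaSpec, CueSet, GoalSpec
from vfgn.pipeline import default_dmp_goals, default_rm_goal
from vfgn.protocol import build_dmp_session, build_rm_session


@pytest.fixture(scope="session")
def arena():
    return ArenaSpec()


@pytest.fixture(scope="session")
def rm_goal():
    return default_rm_goal()


@pytest.fixture()
def rm_session(arena, rm_goal):
    return build_rm_session(arena, CueSet.default(arena, "rm"), rm_goal, seed=11)


@pytest.fixture()
def dmp_session(arena):
    return build_dmp_session(
        arena, CueSet.default(arena, "dmp"), default_dmp_goals(), seed=11
    )


class StraightToGoal:
    """Oracle policy: heads straight at the goal center, points exactly at it."""

    def begin_trial(self, trial):
        self.goal = trial.goal

    def point(self, trial):
        gx, gy = self.goal.center
        return math.degrees(
            math.atan2(gy - trial.start[1], gx - trial.start[0])
        ) % 360.0

    def desired_heading(self, x, y, heading, t):
        gx, gy = self.goal.center
        return math.degrees(math.atan2(gy - y, gx - x)) % 360.0

    def end_trial(self, trial, entered_goal):
        self.entered = entered_goal


class Stationary:
    """Policy that never moves (and points north)."""

    def begin_trial(self, trial):
        pass

    def point(self, trial):
        return 90.0

    def desired_heading(self, x, y, heading, t):
        return None

    def end_trial(self, trial, entered_goal):
        pass


@pytest.fixture()
def straight_policy():
    return StraightToGoal()


@pytest.fixture()
def stationary_policy():
    return Stationary()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
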
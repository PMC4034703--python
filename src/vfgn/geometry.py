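"""Arena geometry for the virtual water-maze task.

The task takes place in a circular arena enclosed by a featureless wall,
with a hidden circular goal on the floor and three orientation cues near
the wall.  All geometry is 2D Cartesian: origin at the arena center,
coordinates in meters, azimuths in degrees counterclockwise from the +x
axis and normalized to [0, 360).  The goal "quadrant" used for probe-trial
spatial bias is the 90°-wide full-radius sector centered on the goal's
azimuth, so that chance-level occupancy is 25% by symmetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ArenaSpec",
    "GoalSpec",
    "CueSet",
    "normalize_angle",
    "angular_difference",
    "azimuth_of",
    "in_goal",
    "goal_quadrant",
    "quadrant_index",
    "Sector",
]


def normalize_angle(deg: float) -> float:
    """Normalize an azimuth in degrees to [0, 360). Idempotent."""
    if not math.isfinite(deg):
        raise ValueError(f"angle must be finite, got {deg!r}")
    r = deg % 360.0
    return 0.0 if r == 360.0 else r  # guard the x % 360 == 360.0 float artifact


def angular_difference(a: float, b: float) -> float:
    """Absolute angular difference between two azimuths, in [0, 180].

    This is the circle metric: the shorter of the two rotations taking
    ``a`` onto ``b``.  Symmetric in its arguments.
    """
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ValueError("angles must be finite")
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def azimuth_of(p, origin=(0.0, 0.0)) -> float:
    """Azimuth of point ``p`` seen from ``origin``, degrees in [0, 360).

    The degenerate case ``p == origin`` maps to 0° by convention (it is
    measure-zero for sampled trajectories and never occurs for validated
    goals/starts).
    """
    dx = p[0] - origin[0]
    dy = p[1] - origin[1]
    return math.degrees(math.atan2(dy, dx)) % 360.0


@dataclass(frozen=True)
class ArenaSpec:
    """Circular arena, center fixed at the origin.

    Default radius 28 m (a 56 m diameter arena, a 20-fold enlargement of a
    2.8 m diameter real-space apparatus).
    """

    radius: float = 28.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not (math.isfinite(self.radius) and self.radius > 0):
            raise ValueError(f"arena radius must be positive, got {self.radius}")
        if tuple(self.center) != (0.0, 0.0):
            raise ValueError("arena center is fixed at the origin")

    def contains(self, p) -> bool:
        return math.hypot(p[0], p[1]) <= self.radius

    def clip(self, p) -> tuple[float, float]:
        """Project a point outside the wall radially back onto the wall."""
        r = math.hypot(p[0], p[1])
        if r <= self.radius:
            return (p[0], p[1])
        s = self.radius / r
        return (p[0] * s, p[1] * s)


@dataclass(frozen=True)
class GoalSpec:
    """Hidden circular goal region.

    Default radius 2.8 m: the goal occupies 10% of the default arena
    diameter, read as a linear extent (goal diameter = 0.1 × arena
    diameter).  ``active`` is cleared for probe trials (entering the goal
    region neither reveals it nor ends the trial); ``visible`` is set for
    the visuo-motor control trial.
    """

    center: tuple[float, float]
    radius: float = 2.8
    active: bool = True
    visible: bool = False

    def __post_init__(self):
        if not (math.isfinite(self.radius) and self.radius > 0):
            raise ValueError(f"goal radius must be positive, got {self.radius}")
        if not all(math.isfinite(c) for c in self.center):
            raise ValueError("goal center must be finite")

    def validate_inside(self, arena: ArenaSpec) -> None:
        """Raise unless the goal circle lies entirely inside the arena."""
        d = math.hypot(*self.center)
        if d + self.radius > arena.radius:
            raise ValueError(
                f"goal circle (center {self.center}, r={self.radius}) "
                f"overlaps the arena wall (R={arena.radius})"
            )


def in_goal(p, goal: GoalSpec) -> bool:
    """True iff ``p`` lies in the goal circle; the boundary counts as inside."""
    return math.hypot(p[0] - goal.center[0], p[1] - goal.center[1]) <= goal.radius


@dataclass(frozen=True)
class Sector:
    """90°-wide angular sector [center − 45°, center + 45°), full radius.

    Lower bound inclusive, upper bound exclusive, so the four sectors
    obtained by rotating in 90° steps partition the disk with no double
    counting at the edges.
    """

    center_azimuth: float
    half_width: float = 45.0

    def contains(self, p) -> bool:
        az = azimuth_of(p)
        rel = (az - (self.center_azimuth - self.half_width)) % 360.0
        return rel < 2 * self.half_width


def goal_quadrant(goal: GoalSpec, arena: ArenaSpec) -> Sector:
    """The arena quadrant containing the goal in its center.

    Raises if the goal sits exactly at the arena center (azimuth undefined).
    """
    d = math.hypot(goal.center[0] - arena.center[0], goal.center[1] - arena.center[1])
    if d == 0.0:
        raise ValueError("goal at arena center: goal azimuth (and quadrant) undefined")
    return Sector(azimuth_of(goal.center, arena.center))


def quadrant_index(p, goal: GoalSpec, arena: ArenaSpec) -> int:
    """Index in {0,1,2,3} of the goal-centered quadrant containing ``p``.

    0 is the goal quadrant; 1, 2, 3 follow counterclockwise.  Exactly one
    index matches any point, by the half-open sector convention.
    """
    theta_g = azimuth_of(goal.center, arena.center)
    d = math.hypot(goal.center[0] - arena.center[0], goal.center[1] - arena.center[1])
    if d == 0.0:
        raise ValueError("goal at arena center: quadrant undefined")
    rel = (azimuth_of(p) - (theta_g - 45.0)) % 360.0
    return int(rel // 90.0)


@dataclass(frozen=True)
class CueSet:
    """Three orientation cues near the circular wall.

    Cues carry only an identity tag (the real task distinguishes cue sets
    between sessions by shape and color; here the tag is the identity).
    Each cue must sit in the radial band [0.9, 1.0]·R.
    """

    positions: tuple[tuple[float, float], ...]
    tags: tuple[str, ...] = ("cue1", "cue2", "cue3")

    def __post_init__(self):
        object.__setattr__(self, "positions", tuple(tuple(p) for p in self.positions))
        object.__setattr__(self, "tags", tuple(self.tags))
        if len(self.positions) != 3 or len(self.tags) != 3:
            raise ValueError("a cue set has exactly 3 cues (and 3 tags)")

    def validate(self, arena: ArenaSpec) -> None:
        for p, tag in zip(self.positions, self.tags):
            r = math.hypot(p[0], p[1])
            if not (0.9 * arena.radius <= r <= arena.radius):
                raise ValueError(
                    f"cue {tag!r} at radial distance {r:.2f} is outside "
                    f"[0.9, 1.0]·R = [{0.9 * arena.radius:.2f}, {arena.radius:.2f}]"
                )

    @classmethod
    def default(cls, arena: ArenaSpec | None = None, tag_prefix: str = "rm") -> "CueSet":
        """Cues at azimuths 90°, 210°, 330° at 0.95·R (120° spacing)."""
        arena = arena or ArenaSpec()
        r = 0.95 * arena.radius
        pos = tuple(
            (r * math.cos(math.radians(a)), r * math.sin(math.radians(a)))
            for a in (90.0, 210.0, 330.0)
        )
        return cls(pos, tuple(f"{tag_prefix}-{i}" for i in (1, 2, 3)))
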
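# Methods

## Task model

The task is simulated in a planar circular arena of radius *R* = 28 m
(origin at the center, coordinates in meters, azimuths in degrees
counterclockwise from +x).  A circular goal of radius 2.8 m — the goal
diameter is 10% of the arena diameter, read as a linear extent — sits on
the floor; three orientation cues with identity tags lie in the radial
band [0.9, 1.0]·R (defaults at azimuths 90°, 210°, 330°, 0.95·R).  The
goal-centered "quadrant" is the full-radius 90° sector centered on the
goal azimuth, lower edge inclusive, upper exclusive; the four rotated
sectors partition the disk, so a spatially unbiased navigator occupies
the goal quadrant 25% of the time.  Radially bounded quadrants are not
used: full-radius sectors are the convention under which the 25% chance
level is exact by symmetry.

Each trial runs a fixed state machine: the navigator stands at the start
point, indicates the believed goal azimuth (all trials except the very
first search of a goal), then moves until it enters an active goal or the
60 s search limit expires.  On timeout the goal is revealed and the
simulator steers the navigator straight to it; this tail is logged with a
`post_reveal` flag and excluded from every metric, since the parameters
measure search and the visible-goal walk would dilute path efficiency.
Probe trials (inactivated goal) always run the full 60 s and end without
reveal or learning event — the protocol leaves the unrewarded search
unreinforced.  The 10 s memorize phase on the goal is represented only as
a learning event delivered to the agent, not as logged motion, and the
approach to the start sphere is not simulated; neither contributes to any
metric.

Start positions sit on the 0.92·R circle at one of eight 45°-grid
azimuths, excluding azimuths within 45° of the goal azimuth and the
previous trial's start (at least four candidates always remain).  The
grid is an implementation choice standing in for "pseudo-randomized"
starts; the goal exclusion prevents trivially short approaches.

Kinematics: translation 7 m/s (crosses the arena in ~8 s, leaving
headroom within the 60 s limit), turn rate capped at 90°/s, integration
step dt = 0.1 s.  Positions are clipped to the wall; a navigator pressing
outward slides along it.  The speeds are design values chosen so that a
direct path is comfortably feasible within the limit and a random walk
usually is not.

## Session schedules

* **Reference memory (RM), 11 trials** — T1 free search (no pointing);
  standard trials T2–T5 and T7–T10, scored as four blocks of two; T6
  probe (goal inactivated); T11 visible-goal control (visuo-motor check).
  The goal position is stable throughout.
* **Delayed matching to place (DMP), 18 trials** — acquisition
  A1 A2 A3 B1 B2 B3 C1 C2 C3, where each goal's first trial is an
  announced positional change (no pointing); recall A B C A B C; probe
  A B C with goals inactivated.  The three goal slots are placed 120°
  apart at the same radial distance, so each bears the same geometric
  relation to its nearest cue.

## Navigator model

The memory navigator stores, per goal, the true position observed the
last time a trial ended standing on that goal (including after a timeout
reveal), an observation count `n_obs`, and a `staleness` counter that
increments once per intervening trial of a different goal and resets on
observation.  On each trial it draws a goal estimate

    estimate = stored position + N(0, σ_t² I),
    σ_t = memory_sd0 · memory_decay^(n_obs − 1) + forget_sd · staleness,

points at the estimate's azimuth plus `N(0, pointing_sd²)`, walks
straight to the estimate, and then searches locally along an outward
Archimedean spiral (pitch = goal radius, so the swept annulus cannot skip
the goal) centered on the estimate, returning inward and re-spiraling
once the spiral radius exceeds a belief-scaled bound
(2·goal radius + min(2 σ_t, 1.5·goal radius)) — a persistent local
search.  With probability `lapse_rate` a trial is instead a pure
exploration lapse; trials for a never-observed goal also fall back to
exploration.  The random explorer is a correlated random walk (heading
noise `heading_sd` per step, default 6°) reflected at the wall, with
uniformly random pointing; it uses no goal information.

Learning rides on observation *count*, not elapsed time: recall-phase
degradation is generated entirely by the staleness term, mirroring a
protocol that manipulates intervening trials rather than clock time.
Lapses model trial-wise attention failures, not step-wise noise.  The
exponential decay of σ_t is a modeling stand-in — the task data cannot
constrain the functional form of learning — and is isolated behind the
policy interface.

### Parameters and shipped presets

| parameter | units | healthy_like | impaired_like | meaning |
|---|---|---|---|---|
| pointing_sd | deg | 8 | 12 | angular noise on the pointed direction |
| memory_sd0 | m | 12 | 18 | estimate spread after one observation |
| memory_decay | – | 0.75 | 0.85 | multiplicative shrink per extra observation |
| forget_sd | m | 0.2 | 10 | spread added per intervening other-goal trial |
| heading_sd | deg/step | 6 | 6 | random-walk heading noise |
| lapse_rate | – | 0.02 | 0.12 | probability of a pure-exploration trial |

Cohorts draw per-subject parameters from Gaussian spreads around the
preset means (clipped to valid ranges); ages are uniform on [18, 35], the
recruitment band of a typical first-episode cohort, and an optional
`age_slope_memory_sd0` makes memory noise grow with age for
age-correlation studies.  The preset values were fixed by calibration
runs at the study group size (n = 29 per group): they are the smallest
perturbation of the healthy profile that robustly reproduces the
qualitative group pattern — higher pointing error across RM blocks, lower
probe quadrant preference yet above chance, and a recall-phase drop after
the DMP acquisition→recall delay that healthy agents do not show.  The
presets make no claim of cognitive realism and are not fitted to any
human learning curve beyond that qualitative ordering.

## Metrics

* **Pointing error** — absolute angular difference between the pointed
  azimuth and the start→goal-center azimuth, in [0, 180]°.  Absent when
  pointing was not required.  Recorded in probe trials but not entered
  into block scores.
* **Path efficiency** — `path_min / path_real`, capped at 1, where
  `path_min = ‖start − goal center‖ − goal radius` (distance to the entry
  *boundary*) and `path_real` is the search-phase polyline length up to
  and including the first in-goal sample.  The boundary convention keeps
  the stated range (0, 1] attainable: the search ends at the first
  boundary crossing, so measuring to the center would make 1.0
  unreachable.  Absent when the goal was not found in the search phase.
* **Goal quadrant preference** — fraction of probe-trial samples in the
  goal quadrant.  Samples are weighted equally (trajectories have
  constant dt by construction; variable-dt external logs should be
  resampled first).  The full 60 s is scored by default (subjects search
  the whole trial); the optional `first_seconds` argument restricts
  scoring to the early probe, mirroring rodent analyses — off by default.
* **Entrances** — maximal runs of consecutive in-goal samples; an
  entrance is an out→in transition, and a trajectory starting inside
  counts its initial run.

Latency is deliberately not a metric: the decision about the goal
position is already expressed at pointing time.

## Statistics

All tests are computed from closed-form sums of squares; scipy supplies
only t and F tail probabilities.  The mixed ANOVA is the classical
split-plot decomposition — between effects tested against
subjects-within-groups, within effects and interactions against the
within × subjects residual — with one between factor (optionally a
second, e.g. sex, requiring equal cell sizes).  For balanced designs the
Type I/II/III distinction vanishes; balance (every subject at every
within level) is enforced with an error naming the offending subjects.
Sphericity corrections are not applied (documented limitation; with two
trials per block and four blocks the correction is small but nonzero).
Stepwise range post-hoc procedures are deliberately replaced by pairwise
two-sample t tests with Holm correction, which carry familywise error
guarantees.  Degenerate inputs follow explicit conventions: zero variance
with a nonzero effect reports p = 0 with a warning flag; an all-constant
ANOVA table reports zero SS and F = 0 with a warning rather than failing.

## Validation design and problem sizes

* The chance-level baseline runs the random explorer for 1000 full 60 s
  probe trials.  Its start azimuth is uniform on the start circle rather
  than drawn by the protocol sampler: the protocol's exclusion of starts
  near the goal is a goal-*dependent* rule that biases early-trial
  occupancy away from the goal quadrant by more than the Monte-Carlo
  error at this n, whereas with goal-independent starts the walk is
  rotationally exchangeable and its expected goal-quadrant occupancy is
  exactly 0.25.
* Group-contrast checks run full-kinematics cohorts of 29 agents per
  group (the study group size) through complete RM and DMP sessions.
* The null calibration of the ANOVA group test uses 1000 replicate
  cohorts of 10 agents per group, both groups drawn from the same preset,
  through the navigator's kinematics-free pointing channel: the pointing
  error of a trial is conditionally independent of the trajectory given
  the per-trial estimate (exactly so when every preceding trial ends on
  the goal, which the timeout reveal guarantees in RM sessions), so the
  reduction reproduces the full model's pointing distribution at a
  fraction of the cost.  A dedicated test checks the reduction against
  the full simulator distributionally.
* The mixed ANOVA is cross-checked against a brute-force sequential
  projection (nested least-squares fits) on toy designs up to
  3 groups × 4 subjects × 4 blocks, and against an independent
  reference implementation; t tests and correlations are checked against
  hand-computed examples and scipy.

Passing these checks shows that the pipeline is internally consistent
and that the generative model produces the intended statistical
structure.  It does not show that the agents are cognitively realistic:
the synthetic cohorts have no strategy switching, no thigmotaxis, no
within-trial speed modulation, and their learning curve shape is assumed,
not estimated.  Conclusions about real subjects require real data; the
package's role is to exercise and validate the machinery around them.

## Known limitations

* No 3D rendering, physics or interactive mode; the pre-training
  labyrinth and clinical/neuropsychological batteries are out of scope.
* Inter-trial intervals are not modeled as wall-clock time; delay enters
  only through intervening-trial counts.
* Whether the original apparatus capped path efficiency at 1 under the
  boundary/center ambiguity is unknown; this implementation caps.
* The spiral's per-step advance assumes the default kinematics
  (0.7 m per step); non-default speeds change the local-search density
  slightly but not its coverage guarantee.
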
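# Methods

## Vehicle and control model

The vehicle is a point on the plane moving at constant speed v; the only
control variable is the yaw-rate y (rad/s, positive = rightward).  Heading
0 points along +z_world and increases clockwise from above, so the forward
unit vector is (sin h, cos h) and the right unit vector (cos h, −sin h).
One 60 Hz frame applies, in order:

1. **steering-point acquisition** (gaze interpolation or waypoint
   selection),
2. **control law** — proportional y′ = k·arctan(x/z) or pure pursuit
   y′ = k·2vx/(x²+z²) on the egocentric steering point (x, z),
3. **exponential smoothing** y_t = a·y′_t + (1−a)·y_{t−1} with a defined
   per 60 Hz frame,
4. **clipping** to ±35°/s in the slalom configuration (no clipping on the
   S-bend, matching the limits imposed on the respective driving rigs),
5. **semi-implicit Euler step**: rotate the heading by y·dt, then
   translate v·dt along the *new* heading.

Smoothing before clipping is the default order; both stages are pure
functions, so the alternative order can be composed by hand for
sensitivity checks.  With |y| below the limit the pipeline is idempotent.
An optional rate-invariant re-parameterization
a′ = 1 − (1−a)^(60·dt) is provided for non-60 Hz frame periods but is off
by default, since all shipped configurations are frame-locked at 60 Hz.

A model run replays one human trial: it starts from the human's first
recorded pose (position, heading, and yaw-rate — the recorded yaw-rate
seeds the smoother; 0 if absent) and runs exactly as many frames as the
human drive, with no mid-trial corrections.

## Tracks and track position

Both courses are planar (no roll or pitch) and carry a reference line
densely indexed at 0.05 m stations (configurable).  *Track position* of a
world point is the arc length of its nearest station (ties toward smaller
arc length); *lane position* is the signed lateral distance from that
station, positive toward the outer edge of the current curve.  On straight
segments, where "outer" is undefined, positive means right of the
centerline — a documented convention.  A point is *offtrack* when its
absolute lane position exceeds the half-width.

* **Slalom** (exp1): a straight lane of width 3 m, reference length
  12 + 2·8 + 4 = 32 m, waypoints at arc lengths 12/20/28 m with lateral
  offsets +0.75/−0.75/+0.75 m, driven at 8 m/s.  The modeled course is the
  slalom section alone; the surrounding circuit it was embedded in is out
  of scope.  For analyses of real drives the reference line can be
  replaced by the empirical mean path across trials
  (`mean_reference_path`), which averages, at each base-track station,
  each trial's position of closest approach, then re-indexes at 0.05 m.
* **S-bend** (exp2): sixteen tangent-continuous 120° circular arcs of
  radius 50 m and alternating sign, track width 3.5 m, waypoints every
  10.5 m along the centerline, driven at 10.5 m/s.  The first and last
  curves are excluded from the analysis window (acceleration transient and
  left/right balance, respectively), leaving 14 curves.  The original rig
  held the speed only approximately at 10.5 m/s via its physics engine; we
  fix it exactly.

## Gaze processing

Gaze is represented as (azimuth, elevation) in degrees relative to the
locomotor heading and the horizon.  A below-horizon ray from eye height
e = 1.2 m intersects the ground at distance d = e/tan(−elevation); the
*point of fixation* is that intersection in world coordinates.  Rays at or
above the horizon have no forward ground intersection and are flagged
invalid.  Valid rays within ~0.35° of the horizon are capped at 200 m
ground distance: foreshortening makes such projections numerically
explosive, and the cap (exposed in the API) keeps the controllers stable
without affecting ordinary samples.

A whole trial is excluded when strictly more than 10% of its samples have
elevation above −2°.  Within an included trial, invalid samples are
bridged by interpolating between neighboring valid samples (a
hold-last-point alternative follows from querying the interpolator at the
last valid position); only whole trials are ever excluded.

Fixation points are interpolated componentwise in world coordinates as a
function of the *human's track position*, and queried at the *model's*
track position — interpolating by position rather than time prevents error
accumulation when the model takes a longer or shorter path than the human.
For the slalom with real data this indexing would use the empirical mean
path, consistent with how track position is defined there.

## Steering-point policies

Degenerate inputs are resolved by explicit policies:

* a fixation that reprojects behind the model vehicle (z ≤ 0) falls back
  to the last valid steering point; if none exists yet, the target
  yaw-rate decays toward zero through the smoother;
* a model that outruns the gaze recording (track position beyond the last
  sample) likewise holds the last valid steering point;
* in waypoint mode, the active waypoint advances while the vehicle is
  strictly closer than th·v, never retreats, and saturates at the last
  waypoint.  Once the *final* waypoint is reached (switch radius entered
  or passed behind), the model steers toward the reference line ~2 s ahead:
  the slalom course is modeled standalone, but on the longer course it
  stands in for, further waypoints would have continued ahead, and holding
  a frozen egocentric target instead would feed the commanded yaw back
  into itself and spiral the vehicle off the lane end.

## Metrics

* **Trajectory error**: both trajectories are resampled onto the
  reference-line stations they jointly cover (position of closest approach
  per station, restricted to the analysis window); the error is the mean
  Euclidean distance between paired positions.  Resampling against
  discrete 60 Hz samples leaves sub-millimeter tie-break noise at stations
  halfway between samples.
* **Offtrack percentage**: share of frames (within the analysis window)
  with |lane position| beyond the half-width.
* **Yaw-rate correlation**: Pearson r between the frame-locked model and
  human yaw-rate series, aligned by frame index (both series have equal
  length by construction).  Zero-variance series yield NaN, which is
  excluded from averages and logged, never coerced to 0.
* **Landmark trajectory correlations**: per participant and landmark
  station (the slalom waypoints' stations; the S-bend window's beginning,
  middle, and end), Pearson r across trials between human and model lane
  positions at the frame of closest approach to the station.

Aggregation is participant-first and unweighted by trial count: trial
values are averaged within participants, participant values averaged
across participants.  Correlations are averaged on the Fisher-z scale
(|r| capped at 1−10⁻¹² before atanh) and back-transformed; this is applied
to yaw-rate correlations as well as landmark correlations, and
`fisher_mean` is exposed so an arithmetic alternative is one line away.

## Parameter optimization

The objective is the grand mean trajectory error of one shared parameter
vector over all trials of all participants (pooled fitting; per-participant
fitting is possible by passing subsets but is not the shipped procedure).
The search runs a full grid over k ∈ [0.9, 3], a ∈ [0.05, 1] (and
th ∈ [0.1, 0.8] for waypoint input) at 8 points per axis, then refines the
grid argmin with Nelder–Mead (xatol = fatol = 10⁻³, ≤200 iterations).
Out-of-box simplex proposals are clamped to the box and penalized by +1 m
to keep a and th physically meaningful; a failed simulation contributes a
large finite penalty (10³ m) so the search can continue.  If the simplex
somehow ends worse than the grid argmin, the argmin is returned —
refinement never worsens.  The procedure is deterministic given the
dataset and search space.

The grid density matters: gain and smoothing trade off along a ridge
(large k with small a approximates smaller k with larger a over short
horizons), and a simplex started too far from the truth can settle on the
ridge.  Eight points per axis reliably starts the simplex in the correct
basin on the synthetic datasets.

## Synthetic data

The generator emulates the descriptive statistics of steering gaze, not
any particular human: fixation episodes last ~0.5 s and track a *fixed
world point* (the egocentric angles rotate as the vehicle moves — smooth
pursuit); saccades retarget to a point 1–3 s of time headway ahead on the
reference line, or, in slalom mode, to the upcoming waypoint nearest the
sampled headway; with small probabilities an episode is a look-ahead
fixation (double headway) or a near-horizon glance (elevation drawn from
[−2°, 1°]); isotropic Gaussian angular noise (default SD 0.5°, a plausible
eye-tracker accuracy) perturbs every sample.  The synthetic driver closes
the loop by steering toward its own gaze points with a known-parameter
controller plus Gaussian motor noise on the executed yaw-rate (default SD
0.01 rad/s, small relative to the ~0.2 rad/s maneuvers).  Dataset shapes
mirror the two study configurations (11 and 16 participants); all
randomness derives from one master seed through per-participant
substreams.

What this does *not* emulate: calibration bias, steering-decoupled
glances beyond the simple look-ahead/horizon processes, individual gaze
strategies, blinks, or saccade kinematics.  Tests passing on synthetic
data therefore demonstrate the pipeline's correctness and the models'
behavior under the stated assumptions — not that the models capture real
human variability.

## Problem sizes and numerical choices

The test suite and the acceptance script favor small, fast configurations
as a deliberate design choice: synthetic datasets of 2 participants × 1–2
trials identify the parameters well in the noiseless case; the S-bend
property tests use a 4-curve variant with identical per-curve geometry;
the headline offtrack computations run the full 16-curve course once per
controller.  Angles are radians internally and degrees at file
boundaries; headings are wrapped to (−π, π]; the reference-line station
spacing (0.05 m) bounds track-position quantization at half a station.

## Known limitations

* The two control laws are deliberately minimal; two-point PD control,
  model-predictive control, and lateral vehicle dynamics are out of scope.
* Speed is constant; there is no longitudinal control.
* The empirical mean-path discretization ("a few centimeters") means
  centimeter-level differences against any externally produced reference
  path are expected.
* Whether clipping preceded or followed smoothing in the original rigs is
  not documented; clip-after-smooth is the default here and the
  alternative is composable from the exported primitives.
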
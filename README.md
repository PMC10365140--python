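# gazesteer

Can gaze direction alone steer a vehicle?  Drivers look 1–3 s ahead at
points on the ground they intend to pass through.  `gazesteer` tests
whether that oculomotor signal carries enough information to close the
steering loop: it simulates a constant-speed vehicle whose only input is a
*steering point* — either the driver's point of fixation projected onto
the plane of travel, or an optical waypoint on the course — and compares
the simulated trajectories against the (here: synthetically generated)
human ones.

The package is a library for researchers in visuomotor control and
driver modeling, with a thin `gazesteer` command-line front end.

## Models

Two control laws map an egocentric steering point (x, z) — lateral and
forward offsets from the vehicle, in meters — to a target yaw-rate y′:

* **Proportional control** on the horizontal visual angle
  h = arctan(x/z):

      y′ = k · h

  Pure direction control: depth is ignored.

* **Pure pursuit**: the constant yaw-rate that would carry the vehicle to
  the point along a circular arc tangent to its current heading at
  speed v:

      y′ = k · 2·v·x / (x² + z²)

The target is exponentially smoothed per 60 Hz frame,
y_t = a·y′_t + (1−a)·y_{t−1}, optionally clipped to ±35°/s (slalom
configuration), and integrated by a semi-implicit Euler step (turn, then
translate v·dt along the new heading).

Steering points come from one of two inputs:

* **gaze** — points of fixation (gaze ray ∩ ground plane) recorded along
  the human drive, linearly interpolated *by track position* so the model
  is given "where the human looked from here" no matter how its own
  trajectory evolves;
* **waypoints** — the course's visible waypoint markers, with the active
  waypoint switching to the next one once the vehicle is closer than
  th·v (th is a time-headway parameter in seconds).

Two parametric courses are built in: a straight 3 m slalom lane with three
waypoints 8 m apart at ±0.75 m lateral offset (driven at 8 m/s), and an
S-bend of sixteen 120° arcs of 50 m radius with waypoints every 10.5 m on
an invisible 3.5 m track (driven at 10.5 m/s; first and last curves
excluded from analysis).

Parameters (k, a, and th for waypoint input) are fitted by grid search
over k ∈ [0.9, 3], a ∈ [0.05, 1], th ∈ [0.1, 0.8] followed by Nelder–Mead,
minimizing the grand mean trajectory error (participant-wise mean of
per-trial mean distance between model and human positions matched by track
position, then averaged unweighted across participants).

Because no human recordings ship with the package, a synthetic generator
(`gazesteer.synth`) produces gaze scanpaths with the stereotypical
pursuit–saccade structure (~0.5 s pursuit of a fixed ground point, saccade
to a new point 1–3 s ahead, occasional look-ahead fixations and horizon
glances, Gaussian angular noise) and closed-loop "human" drivers with
known controller parameters and motor noise — so every pipeline stage is
testable against ground truth.

## Worked example

```python
import gazesteer as gs

# synthetic slalom dataset: 2 participants x 2 trials, default noise
cfg = gs.default_config("exp1", n_participants=2, trials_per_participant=2, seed=42)
trials = gs.generate_dataset("exp1", cfg)

# replay each trial with the gaze-guided pure-pursuit model
params = gs.reference_params("gaze", "pure_pursuit", "exp1")
results = [gs.run_trial(t, params, "pure_pursuit", "gaze") for t in trials]

summary = gs.summarize(results, trials)
print(f"grand mean error : {summary.grand_mean_error:.3f} m")
print(f"mean offtrack    : {summary.mean_offtrack_pct:.2f} %")
print(f"mean yaw-rate r  : {summary.mean_yawrate_r:.3f}")
```

prints

```
grand mean error : 0.066 m
mean offtrack    : 1.43 %
mean yaw-rate r  : 0.976
```

The grand mean error is the average distance between the model's and the
synthetic driver's positions at matched track positions (small here, since
the generating driver uses the same control law); offtrack is the share of
frames spent beyond the lane edges; the yaw-rate correlation measures how
similar the steering *activity* is frame by frame.

The same pipeline is available from the shell:

```sh
gazesteer synth --experiment exp1 --seed 42 --out data/
gazesteer metrics --dataset data/ --experiment exp1 --out out/
```

which writes a four-row summary table (two controllers × two inputs) to
`out/summary.csv`.

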
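"""Synthetic gaze scanpaths and driver trajectories with known ground truth.

The generator emulates the gaze pattern observed during steering: smooth
pursuit of a point on the ground for roughly half a second, then a saccade
to a new point 1-3 s of time headway ahead, occasionally replaced by a
look-ahead fixation about twice as far or by a glance near/above the
horizon.  During a pursuit episode the *world* target stays fixed while
the egocentric gaze angles rotate as the vehicle moves.  Gaussian angular
noise perturbs each sample.

The synthetic "human" driver is itself a closed-loop controller with known
parameters steering toward its own gaze points, with optional Gaussian
motor noise on the yaw-rate — so model runs and parameter fits can be
checked against a known generative truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .controllers import (
    PURE_PURSUIT,
    YAW_LIMIT_SLALOM,
    ControllerParams,
    clip_yaw,
    smooth_yaw,
    yaw_target,
)
from .errors import InvalidParameterError
from .gaze import (
    GazeRecord,
    SteeringPoint,
    ego_from_world,
    fixation_from_gaze_angles,
    gaze_angles_from_fixation,
)
from .sim import Trial
from .sim import step_vehicle
from .tracks import (
    Pose,
    TrackGeometry,
    build_sbend_track,
    build_slalom_track,
    closest_track_index,
)

#: Speeds of the two study configurations (m/s).
SPEED_SLALOM = 8.0
SPEED_SBEND = 10.5

#: Participant counts of the two study configurations.
N_PARTICIPANTS = {"exp1": 11, "exp2": 16}


@dataclass
class SyntheticConfig:
    """Ground-truth driver parameters and scanpath statistics.

    Defaults follow the descriptive statistics of steering gaze: ~0.5 s
    pursuit episodes, targets 1-3 s of time headway ahead, occasional
    look-ahead fixations (double headway) and horizon glances, and small
    angular noise on each gaze sample.
    """

    driver_params: ControllerParams
    controller: str = PURE_PURSUIT
    pursuit_duration: float = 0.5        # seconds per fixation episode
    headway_range: tuple[float, float] = (1.0, 3.0)   # seconds ahead
    lookahead_prob: float = 0.05         # per-fixation look-ahead probability
    horizon_glance_prob: float = 0.02    # per-fixation near-horizon glance
    gaze_noise_sd: float = 0.5           # degrees, isotropic angular noise
    motor_noise_sd: float = 0.01         # rad/s added to the executed yaw-rate
    fixate_waypoints: bool = False       # slalom-style gaze: target waypoints
    n_participants: int | None = None    # default: study-matched count
    trials_per_participant: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.lookahead_prob, self.horizon_glance_prob):
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError("probabilities must be in [0, 1]")
        if self.gaze_noise_sd < 0 or self.motor_noise_sd < 0:
            raise InvalidParameterError("noise SDs must be >= 0")
        if self.pursuit_duration <= 0:
            raise InvalidParameterError("pursuit_duration must be > 0")


def default_config(experiment: str = "exp1", **overrides) -> SyntheticConfig:
    """Study-matched defaults for either configuration."""
    if experiment == "exp1":
        params = ControllerParams(
            k=1.24, a=0.06, v=SPEED_SLALOM, yaw_limit=YAW_LIMIT_SLALOM
        )
    elif experiment == "exp2":
        params = ControllerParams(k=1.24, a=0.06, v=SPEED_SBEND)
    else:
        raise InvalidParameterError(f"unknown experiment {experiment!r}")
    cfg = SyntheticConfig(driver_params=params, fixate_waypoints=experiment == "exp1")
    return replace(cfg, **overrides) if overrides else cfg


def default_track(experiment: str) -> TrackGeometry:
    if experiment == "exp1":
        return build_slalom_track()
    if experiment == "exp2":
        return build_sbend_track()
    raise InvalidParameterError(f"unknown experiment {experiment!r}")


class _Scanpath:
    """Per-frame gaze process: pursuit episodes with saccadic retargeting."""

    def __init__(self, track: TrackGeometry, cfg: SyntheticConfig, rng: np.random.Generator):
        self.track = track
        self.cfg = cfg
        self.rng = rng
        self.frames_left = 0
        self.target: np.ndarray | None = None
        self.horizon_elevation: float | None = None

    def _new_episode(self, s_now: float) -> None:
        cfg = self.cfg
        self.frames_left = max(
            1, int(round(cfg.pursuit_duration / cfg.driver_params.dt))
        )
        self.horizon_elevation = None
        headway = self.rng.uniform(*cfg.headway_range)
        if self.rng.random() < cfg.lookahead_prob:
            headway *= 2.0
        if self.rng.random() < cfg.horizon_glance_prob:
            # Degenerate near-horizon glance; elevation drawn at or above -2 deg.
            self.horizon_elevation = self.rng.uniform(-2.0, 1.0)
            return
        s_target = min(s_now + headway * cfg.driver_params.v, self.track.length)
        if cfg.fixate_waypoints and len(self.track.waypoint_s):
            # Slalom-style gaze: fixate the waypoint nearest the sampled
            # headway (never one already passed); fall back to the lane
            # continuation once all waypoints lie behind.
            ahead = np.nonzero(self.track.waypoint_s > s_now + 1e-9)[0]
            if len(ahead):
                j = ahead[np.argmin(np.abs(self.track.waypoint_s[ahead] - s_target))]
                self.target = self.track.waypoints[int(j)]
                return
        self.target = self.track.point_at(s_target)

    def sample(self, pose: Pose, t: float, s_now: float) -> GazeRecord:
        if self.frames_left == 0 or (
            self.target is None and self.horizon_elevation is None
        ):
            self._new_episode(s_now)
        self.frames_left -= 1
        cfg = self.cfg
        if self.horizon_elevation is not None:
            azimuth = float(self.rng.normal(0.0, max(cfg.gaze_noise_sd, 1e-12)))
            elevation = self.horizon_elevation
        else:
            azimuth, elevation = gaze_angles_from_fixation(pose, self.target)
        if cfg.gaze_noise_sd > 0:
            azimuth += float(self.rng.normal(0.0, cfg.gaze_noise_sd))
            elevation += float(self.rng.normal(0.0, cfg.gaze_noise_sd))
        return fixation_from_gaze_angles(
            pose, azimuth, elevation, t=t, s_human=s_now
        )


def generate_gaze_sequence(
    track: TrackGeometry,
    trajectory: list[Pose],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> list[GazeRecord]:
    """Gaze records along an existing trajectory, one per 60 Hz frame."""
    scan = _Scanpath(track, cfg, rng)
    dt = cfg.driver_params.dt
    records = []
    for i, pose in enumerate(trajectory):
        s_now = closest_track_index(pose, track)
        records.append(scan.sample(pose, i * dt, s_now))
    return records


def generate_human_trial(
    track: TrackGeometry,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    experiment: str = "exp1",
    participant_id: str = "p0",
    trial_id: str = "0",
    start_lane_offset: float = 0.0,
    start_heading_offset: float = 0.0,
) -> Trial:
    """Closed-loop synthetic drive: the driver steers toward its own gaze.

    Per frame: sample a gaze record from the scanpath process, convert the
    fixation to an egocentric steering point, apply the ground-truth
    control law (target -> smooth -> clip), add motor noise, and step the
    kinematics.  The drive ends when the driver reaches the end of the
    reference line.
    """
    params = cfg.driver_params
    scan = _Scanpath(track, cfg, rng)
    pose = Pose(
        x=float(track.reference_xy[0, 0]) + start_lane_offset,
        z=float(track.reference_xy[0, 1]),
        heading=start_heading_offset,
        yaw_rate=0.0,
    )
    s_stop = track.length - 0.5 * params.v * params.dt
    max_frames = int(2.0 * track.length / (params.v * params.dt)) + 60

    poses: list[Pose] = []
    records: list[GazeRecord] = []
    last_sp: SteeringPoint | None = None
    for i in range(max_frames):
        s_now = closest_track_index(pose, track)
        if s_now >= s_stop:
            break
        rec = scan.sample(pose, i * params.dt, s_now)
        records.append(rec)
        if rec.valid:
            sp = ego_from_world(rec.fixation, pose)
            if sp.behind and last_sp is not None:
                sp = last_sp
        else:
            sp = last_sp
        if sp is None:
            sp = ego_from_world(
                track.point_at(min(s_now + 2.0 * params.v, track.length)), pose
            )
        y_t = yaw_target(cfg.controller, sp, params)
        if not sp.behind:
            last_sp = sp
        y = clip_yaw(smooth_yaw(y_t, pose.yaw_rate, params.a), params.yaw_limit)
        if cfg.motor_noise_sd > 0:
            y += float(rng.normal(0.0, cfg.motor_noise_sd))
        poses.append(pose)
        pose = step_vehicle(pose, y, params.v, params.dt)
    return Trial(participant_id, trial_id, experiment, poses, records, track, v=params.v)


def generate_dataset(
    experiment: str,
    cfg: SyntheticConfig | None = None,
    track: TrackGeometry | None = None,
) -> list[Trial]:
    """A study-shaped dataset of synthetic participants and trials.

    Every participant draws an independent RNG substream from the master
    seed; small random initial lane/heading offsets differentiate trials.
    """
    cfg = cfg or default_config(experiment)
    track = track or default_track(experiment)
    n_participants = cfg.n_participants or N_PARTICIPANTS[experiment]
    master = np.random.SeedSequence(cfg.seed)
    trials = []
    for p, ss in enumerate(master.spawn(n_participants)):
        rng = np.random.default_rng(ss)
        for t in range(cfg.trials_per_participant):
            trials.append(
                generate_human_trial(
                    track,
                    cfg,
                    rng,
                    experiment=experiment,
                    participant_id=f"p{p:02d}",
                    trial_id=str(t),
                    start_lane_offset=float(rng.uniform(-0.3, 0.3)),
                    start_heading_offset=float(rng.uniform(-0.03, 0.03)),
                )
            )
    return trials
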
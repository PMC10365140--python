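"""Kinematic vehicle simulation and whole-trial model runs.

The vehicle is a point moving at constant speed on the plane; the only
control is yaw-rate.  One 60 Hz frame applies semi-implicit Euler: turn
first, then translate along the new heading.  A model run replays a human
trial: it starts from the human's recorded initial pose and steers frame
by frame toward a steering point supplied either from the human's gaze
(interpolated by the *model's* own track position) or from the optical
waypoints with a time-headway switching rule (the active waypoint advances
once the vehicle is closer than ``th * v``).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from .controllers import (
    PROPORTIONAL,
    PURE_PURSUIT,
    ControllerParams,
    clip_yaw,
    smooth_yaw,
    yaw_target,
)
from .errors import (
    BehindObserverError,
    ExtrapolationError,
    InvalidInputError,
    SimulationError,
)
from .gaze import GazeInterpolator, GazeRecord, SteeringPoint, ego_from_world
from .tracks import Pose, TrackGeometry, closest_track_index, offtrack, wrap_angle

GAZE = "gaze"
WAYPOINTS = "waypoints"
INPUT_MODES = (GAZE, WAYPOINTS)


@dataclass
class Trial:
    """One human drive: pose series at 60 Hz, gaze records, track."""

    participant_id: str
    trial_id: str
    experiment: str               # "exp1" | "exp2"
    poses: list[Pose]
    gaze: list[GazeRecord]
    track: TrackGeometry
    v: float | None = None        # nominal constant speed (m/s), if known


@dataclass
class SimulationResult:
    """Model-driven pose/steering-point series aligned to a source trial."""

    poses: list[Pose]
    steering_points: list[SteeringPoint]
    s_track: np.ndarray
    offtrack_flags: np.ndarray
    source: Trial
    model: str                    # "<controller>+<input_mode>"

    @property
    def positions(self) -> np.ndarray:
        return np.array([[p.x, p.z] for p in self.poses]).reshape(-1, 2)

    @property
    def yaw_rates(self) -> np.ndarray:
        return np.array([p.yaw_rate for p in self.poses])


def step_vehicle(pose: Pose, y: float, v: float, dt: float) -> Pose:
    """Advance one frame: rotate by ``y * dt``, translate ``v * dt`` forward."""
    if dt <= 0 or v <= 0:
        raise InvalidInputError("v and dt must be > 0")
    heading = wrap_angle(pose.heading + y * dt)
    return Pose(
        x=pose.x + v * dt * math.sin(heading),
        z=pose.z + v * dt * math.cos(heading),
        heading=heading,
        yaw_rate=y,
    )


def active_waypoint(
    pose: Pose, waypoints: np.ndarray, current_index: int, v: float, th: float
) -> int:
    """Advance the active waypoint while closer than ``th * v`` (strictly).

    The index never decreases and saturates at the last waypoint.
    """
    n = len(waypoints)
    if n == 0:
        raise InvalidInputError("empty waypoint list")
    idx = current_index
    pos = pose.position
    while idx < n and float(np.hypot(*(waypoints[idx] - pos))) < th * v:
        idx += 1
    return min(idx, n - 1)


def time_headway(distance: float, v: float) -> float:
    """Time to cover ``distance`` at speed ``v`` (seconds)."""
    if v <= 0:
        raise InvalidInputError("v must be > 0")
    return distance / v


def gaze_steering_point(
    pose: Pose,
    s_model: float,
    gaze: list[GazeRecord] | GazeInterpolator,
    last_valid: SteeringPoint | None = None,
) -> SteeringPoint:
    """Egocentric steering point from interpolated gaze at ``s_model``.

    A fixation that reprojects behind the model vehicle falls back to
    ``last_valid`` when available.
    """
    if not isinstance(gaze, GazeInterpolator):
        gaze = GazeInterpolator(gaze)
    sp = ego_from_world(gaze(s_model), pose)
    if sp.behind and last_valid is not None:
        return last_valid
    return sp


def run_trial(
    trial: Trial,
    params: ControllerParams,
    controller: str = PURE_PURSUIT,
    input_mode: str = GAZE,
) -> SimulationResult:
    """Run one model variant over one trial, frame-locked to the human drive.

    The model starts at the human's first recorded pose (position, heading
    and yaw-rate) and runs exactly ``len(trial.poses)`` frames; a missing
    or behind-the-observer steering point holds the last valid one.
    """
    if input_mode not in INPUT_MODES:
        raise InvalidInputError(f"unknown input mode {input_mode!r}")
    tag = f"{controller}+{input_mode}"
    n = len(trial.poses)
    if n == 0:
        return SimulationResult(
            [], [], np.empty(0), np.empty(0, dtype=bool), trial, tag
        )

    track = trial.track
    pose = copy.copy(trial.poses[0])
    wp_idx = _initial_waypoint(track, pose) if input_mode == WAYPOINTS else 0
    interp = GazeInterpolator(trial.gaze) if input_mode == GAZE else None
    last_sp: SteeringPoint | None = None

    poses: list[Pose] = []
    sps: list[SteeringPoint] = []
    s_series = np.empty(n)
    off = np.empty(n, dtype=bool)

    finished = False  # final waypoint reached; no steering target remains
    for i in range(n):
        s_i = closest_track_index(pose, track)
        if input_mode == WAYPOINTS:
            wp_idx = active_waypoint(pose, track.waypoints, wp_idx, params.v, params.th)
            sp = ego_from_world(track.waypoints[wp_idx], pose)
            if wp_idx == len(track.waypoints) - 1:
                dist = float(np.hypot(*(track.waypoints[wp_idx] - pose.position)))
                if sp.behind or dist < params.th * params.v:
                    # Final waypoint reached: steer toward the continuation
                    # of the lane (reference line ~2 s ahead) as the next
                    # waypoint would lie there on a longer course.
                    finished = True
            if finished:
                ahead = track.point_at(min(s_i + 2.0 * params.v, track.length))
                sp = ego_from_world(ahead, pose)
            if sp.behind and last_sp is not None:
                sp = last_sp
        else:
            try:
                sp = gaze_steering_point(pose, s_i, interp, last_sp)
            except ExtrapolationError as exc:
                if last_sp is None:
                    raise SimulationError(f"frame {i}: {exc}") from exc
                sp = last_sp
        if sp.behind:
            y_t = 0.0  # no usable target anywhere: let the yaw-rate decay
        else:
            try:
                y_t = yaw_target(controller, sp, params)
            except BehindObserverError as exc:
                raise SimulationError(
                    f"frame {i}: steering point behind observer with no fallback"
                ) from exc
        if not sp.behind:
            last_sp = sp
        y = clip_yaw(smooth_yaw(y_t, pose.yaw_rate, params.a), params.yaw_limit)

        poses.append(pose)
        sps.append(sp)
        s_series[i] = s_i
        off[i] = offtrack(pose, track)
        pose = step_vehicle(pose, y, params.v, params.dt)

    return SimulationResult(poses, sps, s_series, off, trial, tag)


def _initial_waypoint(track: TrackGeometry, pose: Pose) -> int:
    """First waypoint whose arc length exceeds the starting track position."""
    s0 = closest_track_index(pose, track)
    ahead = np.nonzero(track.waypoint_s > s0)[0]
    return int(ahead[0]) if len(ahead) else len(track.waypoint_s) - 1


def centerline_trial(
    track: TrackGeometry,
    v: float,
    dt: float = 1.0 / 60.0,
    experiment: str = "exp1",
    participant_id: str = "centerline",
    trial_id: str = "0",
) -> Trial:
    """Reference drive that follows the track centerline exactly at speed v.

    Poses are sampled every ``v * dt`` of arc length with tangent headings
    and finite-difference yaw-rates; useful as the initial condition for
    waypoint-mode model runs and as a noiseless "human" stand-in.
    """
    step = v * dt
    s = np.arange(0.0, track.length + 1e-9, step)
    pts = track.point_at(s)
    d = np.gradient(pts, axis=0)
    headings = np.unwrap(np.arctan2(d[:, 0], d[:, 1]))
    yaw = np.gradient(headings) / dt
    poses = [
        Pose(x=pts[i, 0], z=pts[i, 1], heading=headings[i], yaw_rate=yaw[i])
        for i in range(len(s))
    ]
    return Trial(participant_id, trial_id, experiment, poses, [], track, v=v)
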
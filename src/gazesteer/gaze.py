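"""Points of fixation on the ground plane and egocentric reprojection.

Gaze is handled in two spaces: (azimuth, elevation) angles relative to the
locomotor heading and the horizon, and the world-frame *point of fixation*
where the gaze ray intercepts the plane of travel.  A below-horizon ray
from eye height ``e`` at elevation ``-b`` hits the ground at distance
``e / tan(b)`` ahead.  Fixations are keyed by the driver's track position
so a model vehicle can look up "where the human was looking from here"
regardless of elapsed time, and world points are reprojected into the
model's egocentric frame as steering points with horizontal visual angle
``h = arctan(x / z)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientGazeError, InvalidInputError, ExtrapolationError
from .tracks import Pose

#: Default eye height above the ground plane (meters).
EYE_HEIGHT = 1.2

#: Ground-distance cap (meters) for valid near-horizon samples.
DISTANCE_CAP = 200.0

#: Elevation (degrees) above which the capped projection kicks in;
#: tan(0.35 deg) ~ 1.2 / 200.
CAP_ELEVATION_DEG = -math.degrees(math.atan(EYE_HEIGHT / DISTANCE_CAP))

#: Whole-trial exclusion rule: a trial is dropped when more than
#: ``EXCLUDE_MAX_FRACTION`` of its samples lie above ``EXCLUDE_THRESHOLD_DEG``.
EXCLUDE_THRESHOLD_DEG = -2.0
EXCLUDE_MAX_FRACTION = 0.10


@dataclass
class GazeRecord:
    """One gaze sample: fixation point on the ground keyed by track position."""

    t: float                  # seconds
    s_human: float            # driver's track position at sample time (m)
    fixation_x: float         # world x of line-of-sight / ground intercept
    fixation_z: float         # world z of the intercept
    elevation: float          # degrees relative to the horizon (negative = below)
    valid: bool = True

    @property
    def fixation(self) -> np.ndarray:
        return np.array([self.fixation_x, self.fixation_z])


@dataclass
class SteeringPoint:
    """Egocentric steering target: lateral x (positive right), forward z."""

    x_ego: float
    z_ego: float
    behind: bool = False

    @property
    def h(self) -> float:
        """Horizontal visual angle from locomotor heading (radians)."""
        return math.atan(self.x_ego / self.z_ego)

    @property
    def distance(self) -> float:
        return math.hypot(self.x_ego, self.z_ego)


def fixation_from_gaze_angles(
    pose: Pose,
    azimuth: float,
    elevation: float,
    eye_height: float = EYE_HEIGHT,
    t: float = 0.0,
    s_human: float = 0.0,
    distance_cap: float = DISTANCE_CAP,
) -> GazeRecord:
    """Project a gaze direction to its point of fixation on the ground plane.

    ``azimuth`` is in degrees clockwise from the locomotor heading,
    ``elevation`` in degrees relative to the horizon (negative = below).
    Rays at or above the horizon produce an invalid record (they would
    project behind the driver); valid rays closer than ``CAP_ELEVATION_DEG``
    to the horizon are capped at ``distance_cap`` meters.
    """
    if eye_height <= 0:
        raise InvalidInputError("eye_height must be > 0")
    if elevation >= 0.0:
        return GazeRecord(t, s_human, math.nan, math.nan, elevation, valid=False)
    d = eye_height / math.tan(-math.radians(elevation))
    d = min(d, distance_cap)
    direction = pose.heading + math.radians(azimuth)
    fx = pose.x + d * math.sin(direction)
    fz = pose.z + d * math.cos(direction)
    return GazeRecord(t, s_human, fx, fz, elevation, valid=True)


def exclude_trial(
    records: list[GazeRecord],
    threshold_deg: float = EXCLUDE_THRESHOLD_DEG,
    max_fraction: float = EXCLUDE_MAX_FRACTION,
) -> bool:
    """Whole-trial exclusion: too many samples too close to the horizon.

    A trial is excluded when *strictly more than* ``max_fraction`` of its
    samples have elevation above ``threshold_deg``.
    """
    if not records:
        raise InvalidInputError("empty gaze record list")
    n_high = sum(1 for r in records if r.elevation > threshold_deg)
    return n_high / len(records) > max_fraction


def _valid_arrays(records: list[GazeRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(s, fx, fz) of valid records, strictly increasing in s."""
    s, fx, fz = [], [], []
    last = -math.inf
    for r in records:
        if not r.valid:
            continue
        if r.s_human <= last:
            continue  # keep the first sample at each track position
        s.append(r.s_human)
        fx.append(r.fixation_x)
        fz.append(r.fixation_z)
        last = r.s_human
    return np.array(s), np.array(fx), np.array(fz)


class GazeInterpolator:
    """Fixation point as a piecewise-linear function of track position.

    Valid records are extracted once; repeated queries (one per simulation
    frame) are then O(log n) lookups.
    """

    def __init__(self, records: list[GazeRecord]):
        self.s, self.fx, self.fz = _valid_arrays(records)
        if len(self.s) < 2:
            raise InsufficientGazeError("need >= 2 valid gaze records")

    def __call__(self, s_model: float) -> np.ndarray:
        if s_model < self.s[0] or s_model > self.s[-1]:
            raise ExtrapolationError(
                f"track position {s_model:.3f} outside gaze coverage "
                f"[{self.s[0]:.3f}, {self.s[-1]:.3f}]"
            )
        return np.array(
            [
                np.interp(s_model, self.s, self.fx),
                np.interp(s_model, self.s, self.fz),
            ]
        )


def interpolate_fixation(s_model: float, records: list[GazeRecord]) -> np.ndarray:
    """Fixation point at track position ``s_model``.

    Componentwise linear interpolation of the world fixation coordinates as
    a function of the human's track position.  Invalid (above-horizon)
    samples are bridged between neighboring valid samples.  For repeated
    queries over the same records build a :class:`GazeInterpolator` once.
    """
    return GazeInterpolator(records)(s_model)


def ego_from_world(p, pose: Pose) -> SteeringPoint:
    """World point -> egocentric steering point (vehicle at origin, +z forward).

    Points with non-positive forward component are flagged ``behind``; the
    caller decides how to handle them.
    """
    d = np.asarray(p, dtype=float) - pose.position
    z_ego = float(np.dot(d, pose.forward))
    x_ego = float(np.dot(d, pose.right))
    return SteeringPoint(x_ego, z_ego, behind=z_ego <= 0.0)


def world_from_ego(sp: SteeringPoint, pose: Pose) -> np.ndarray:
    """Inverse of :func:`ego_from_world`."""
    return pose.position + sp.x_ego * pose.right + sp.z_ego * pose.forward


def gaze_angles_from_fixation(
    pose: Pose, p, eye_height: float = EYE_HEIGHT
) -> tuple[float, float]:
    """(azimuth, elevation) in degrees for a ground point seen from ``pose``."""
    d = np.asarray(p, dtype=float) - pose.position
    dist = float(np.hypot(*d))
    azimuth = math.degrees(
        math.atan2(float(np.dot(d, pose.right)), float(np.dot(d, pose.forward)))
    )
    if dist == 0.0:
        return azimuth, -90.0
    elevation = -math.degrees(math.atan(eye_height / dist))
    return azimuth, elevation
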
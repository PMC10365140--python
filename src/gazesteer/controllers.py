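"""Steering control laws: proportional and pure-pursuit, plus smoothing.

Both laws map an egocentric steering point to a *target* yaw-rate:

* proportional: ``y' = k * h`` with ``h = arctan(x / z)`` — only the
  horizontal visual angle of the target is used, no depth;
* pure pursuit:  ``y' = k * 2 * v * x / (x^2 + z^2)`` — the constant
  yaw-rate that would carry the vehicle to the point along a circular arc
  tangent to its current heading (``2x / (x^2 + z^2)`` is the curvature of
  that arc).

The target is exponentially smoothed per 60 Hz frame,
``y_t = a * y'_t + (1 - a) * y_{t-1}``, and optionally clipped to a
symmetric yaw-rate limit (the slalom setup limits the driver to 35 deg/s;
the S-bend setup does not).  The per-frame order is target -> smooth ->
clip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import (
    BehindObserverError,
    DegenerateTargetError,
    InvalidParameterError,
)
from .gaze import SteeringPoint

#: Simulation frame rate (Hz) to which the smoothing factor is tied.
FRAME_RATE = 60.0

#: Yaw-rate limit (rad/s) used in the slalom configuration.
YAW_LIMIT_SLALOM = math.radians(35.0)

PROPORTIONAL = "proportional"
PURE_PURSUIT = "pure_pursuit"
CONTROLLERS = (PROPORTIONAL, PURE_PURSUIT)


@dataclass
class ControllerParams:
    """Parameters of one model variant.

    ``k`` is the controller gain, ``a`` the per-frame smoothing factor in
    (0, 1], ``th`` the waypoint-switch time headway in seconds (waypoint
    input only), ``yaw_limit`` an optional symmetric yaw-rate bound in
    rad/s, ``v`` the constant speed in m/s and ``dt`` the frame period.
    """

    k: float
    a: float
    v: float
    th: float | None = None
    yaw_limit: float | None = None
    dt: float = 1.0 / FRAME_RATE

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise InvalidParameterError("gain k must be > 0")
        if not 0.0 < self.a <= 1.0:
            raise InvalidParameterError("smoothing factor a must be in (0, 1]")
        if self.th is not None and self.th <= 0:
            raise InvalidParameterError("time headway th must be > 0")
        if self.v <= 0 or self.dt <= 0:
            raise InvalidParameterError("v and dt must be > 0")


def proportional_yaw_target(sp: SteeringPoint, k: float) -> float:
    """Target yaw-rate proportional to the horizontal visual angle."""
    if sp.behind or sp.z_ego <= 0:
        raise BehindObserverError("steering point behind the observer")
    return k * sp.h


def pure_pursuit_yaw_target(sp: SteeringPoint, v: float, k: float) -> float:
    """Constant yaw-rate reaching the point on a circular arc at speed v."""
    d2 = sp.x_ego**2 + sp.z_ego**2
    if d2 == 0.0:
        raise DegenerateTargetError("steering point at the vehicle position")
    return k * 2.0 * v * sp.x_ego / d2


def smooth_yaw(y_target: float, y_prev: float, a: float) -> float:
    """Exponential smoothing toward the target yaw-rate."""
    if not 0.0 <= a <= 1.0:
        raise InvalidParameterError("smoothing factor a must be in [0, 1]")
    return a * y_target + (1.0 - a) * y_prev


def clip_yaw(y: float, yaw_limit: float | None) -> float:
    """Symmetric yaw-rate clipping; identity when no limit is set."""
    if yaw_limit is None:
        return y
    return min(max(y, -yaw_limit), yaw_limit)


def yaw_target(controller: str, sp: SteeringPoint, params: ControllerParams) -> float:
    """Dispatch to the selected control law."""
    if controller == PROPORTIONAL:
        return proportional_yaw_target(sp, params.k)
    if controller == PURE_PURSUIT:
        return pure_pursuit_yaw_target(sp, params.v, params.k)
    raise InvalidParameterError(f"unknown controller {controller!r}")


def rate_invariant_smoothing(a: float, dt: float) -> float:
    """Optional re-parameterization of ``a`` for non-60 Hz frame periods."""
    return 1.0 - (1.0 - a) ** (FRAME_RATE * dt)
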
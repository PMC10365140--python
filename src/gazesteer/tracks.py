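"""Parametric track geometries and arc-length (track-position) queries.

Two experimental geometries are supported:

* a straight-lane *slalom* with three waypoints laterally displaced from
  the centerline (right, left, right), and
* an *S-bend* chain of constant-radius circular arcs of alternating sign
  with waypoints spaced evenly along the centerline.

A track carries a densely indexed reference line (default station spacing
0.05 m).  "Track position" of a world point is the arc length of the
reference station closest to it; lane position is the signed lateral
distance from that station, positive toward the outer edge of the current
curve (positive = right of centerline on straights).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import CoverageError, InvalidGeometryError

#: Default spacing (meters) between consecutive reference-line stations.
INDEX_SPACING = 0.05

TWO_PI = 2.0 * math.pi


def wrap_angle(theta: float) -> float:
    """Wrap an angle to the interval (-pi, pi]."""
    wrapped = math.remainder(theta, TWO_PI)
    if wrapped <= -math.pi:
        wrapped += TWO_PI
    return wrapped


@dataclass
class Pose:
    """Planar vehicle pose.

    Heading 0 points along +z_world and increases clockwise viewed from
    above (positive = rightward), so the forward unit vector is
    ``(sin h, cos h)`` and the right unit vector ``(cos h, -sin h)``.
    """

    x: float
    z: float
    heading: float
    yaw_rate: float = 0.0

    def __post_init__(self) -> None:
        self.heading = wrap_angle(self.heading)

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.z])

    @property
    def forward(self) -> np.ndarray:
        return np.array([math.sin(self.heading), math.cos(self.heading)])

    @property
    def right(self) -> np.ndarray:
        return np.array([math.cos(self.heading), -math.sin(self.heading)])


@dataclass
class TrackGeometry:
    """A densely indexed reference line with edges and ordered waypoints."""

    reference_xy: np.ndarray          # (N, 2) world points (x, z)
    s: np.ndarray                     # (N,) cumulative arc length, increasing
    half_width: float
    waypoints: np.ndarray             # (M, 2) world points
    waypoint_s: np.ndarray            # (M,) arc length of nearest station
    curve_signs: np.ndarray           # (N,) +1 right turn, -1 left, 0 straight
    analysis_window: tuple[float, float]
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.reference_xy = np.asarray(self.reference_xy, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if len(self.s) < 2:
            raise InvalidGeometryError("reference line needs >= 2 points")
        if not np.all(np.diff(self.s) > 0):
            raise InvalidGeometryError("arc length must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.s[-1])

    @property
    def window_empty(self) -> bool:
        lo, hi = self.analysis_window
        return hi <= lo

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.reference_xy)
        return self._tree

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Reference-line point(s) at arc length ``s`` (linear interpolation)."""
        x = np.interp(s, self.s, self.reference_xy[:, 0])
        z = np.interp(s, self.s, self.reference_xy[:, 1])
        return np.stack([x, z], axis=-1)

    def tangent_at_index(self, i: int) -> np.ndarray:
        """Unit tangent of the reference line at station ``i`` (central diff)."""
        lo = max(i - 1, 0)
        hi = min(i + 1, len(self.s) - 1)
        d = self.reference_xy[hi] - self.reference_xy[lo]
        norm = np.hypot(*d)
        if norm == 0.0:
            raise InvalidGeometryError("degenerate reference segment")
        return d / norm


def _station_grid(total_length: float, spacing: float) -> np.ndarray:
    n = int(math.ceil(total_length / spacing - 1e-9))
    return np.linspace(0.0, total_length, n + 1)


def build_slalom_track(
    lane_width: float = 3.0,
    wp_spacing: float = 8.0,
    wp_offset: float = 0.75,
    pre_roll: float = 12.0,
    post_roll: float = 4.0,
    spacing: float = INDEX_SPACING,
) -> TrackGeometry:
    """Straight slalom lane: three waypoints offset (right, left, right).

    The reference line runs along +z from the origin for
    ``pre_roll + 2 * wp_spacing + post_roll`` meters; waypoints sit at arc
    lengths ``pre_roll + i * wp_spacing`` with lateral offsets
    ``(+wp_offset, -wp_offset, +wp_offset)``.
    """
    if lane_width <= 0 or wp_spacing <= 0 or spacing <= 0:
        raise InvalidGeometryError("lane_width, wp_spacing and spacing must be > 0")
    if pre_roll < 0 or post_roll < 0:
        raise InvalidGeometryError("pre_roll and post_roll must be >= 0")
    if abs(wp_offset) >= lane_width / 2:
        raise InvalidGeometryError("waypoint offset must lie inside the lane")

    total = pre_roll + 2.0 * wp_spacing + post_roll
    s = _station_grid(total, spacing)
    xy = np.column_stack([np.zeros_like(s), s])
    wp_s = pre_roll + wp_spacing * np.arange(3.0)
    offsets = wp_offset * np.array([1.0, -1.0, 1.0])
    waypoints = np.column_stack([offsets, wp_s])
    return TrackGeometry(
        reference_xy=xy,
        s=s,
        half_width=lane_width / 2.0,
        waypoints=waypoints,
        waypoint_s=wp_s,
        curve_signs=np.zeros_like(s, dtype=int),
        analysis_window=(0.0, total),
    )


def build_sbend_track(
    radius: float = 50.0,
    arc_deg: float = 120.0,
    n_curves: int = 16,
    width: float = 3.5,
    wp_spacing: float = 10.5,
    spacing: float = INDEX_SPACING,
    first_sign: int = 1,
) -> TrackGeometry:
    """S-bend of ``n_curves`` tangent-continuous arcs of alternating sign.

    Waypoints sit on the centerline every ``wp_spacing`` meters.  The
    analysis window excludes the first and last curve.
    """
    if radius <= 0:
        raise InvalidGeometryError("radius must be > 0")
    if not 0 < arc_deg <= 180:
        raise InvalidGeometryError("arc_deg must be in (0, 180]")
    if n_curves < 2:
        raise InvalidGeometryError("need at least 2 curves")

    arc = math.radians(arc_deg)
    curve_len = radius * arc
    total = n_curves * curve_len
    s = _station_grid(total, spacing)

    # Entry pose of each curve, chained analytically.
    starts = []  # (x, z, heading, sign)
    x, z, h = 0.0, 0.0, 0.0
    for j in range(n_curves):
        sign = first_sign if j % 2 == 0 else -first_sign
        starts.append((x, z, h, sign))
        cx = x + sign * radius * math.cos(h)
        cz = z - sign * radius * math.sin(h)
        h_end = h + sign * arc
        x = cx - sign * radius * math.cos(h_end)
        z = cz + sign * radius * math.sin(h_end)
        h = h_end

    idx = np.minimum((s / curve_len).astype(int), n_curves - 1)
    u = s - idx * curve_len
    xs = np.array([starts[j][0] for j in idx])
    zs = np.array([starts[j][1] for j in idx])
    hs = np.array([starts[j][2] for j in idx])
    sg = np.array([starts[j][3] for j in idx])
    cx = xs + sg * radius * np.cos(hs)
    cz = zs - sg * radius * np.sin(hs)
    hu = hs + sg * u / radius
    xy = np.column_stack(
        [cx - sg * radius * np.cos(hu), cz + sg * radius * np.sin(hu)]
    )

    n_wp = int(math.floor(total / wp_spacing))
    wp_s = wp_spacing * np.arange(1, n_wp + 1)
    wp_s = wp_s[wp_s <= total + 1e-9]
    x_wp = np.interp(wp_s, s, xy[:, 0])
    z_wp = np.interp(wp_s, s, xy[:, 1])
    return TrackGeometry(
        reference_xy=xy,
        s=s,
        half_width=width / 2.0,
        waypoints=np.column_stack([x_wp, z_wp]),
        waypoint_s=wp_s,
        curve_signs=sg.astype(int),
        analysis_window=(curve_len, total - curve_len),
    )


def _as_xy(p) -> np.ndarray:
    if isinstance(p, Pose):
        return p.position
    return np.asarray(p, dtype=float)


def closest_track_index(p, track: TrackGeometry) -> float:
    """Arc length of the reference station closest to world point ``p``.

    Ties are broken toward smaller arc length.
    """
    _, i = track.tree.query(_as_xy(p))
    return float(track.s[i])


def closest_track_indices(points: np.ndarray, track: TrackGeometry) -> np.ndarray:
    """Vectorized :func:`closest_track_index` for an (N, 2) point array."""
    _, idx = track.tree.query(np.asarray(points, dtype=float))
    return track.s[idx]


def _closest_station(p, track: TrackGeometry) -> int:
    _, i = track.tree.query(_as_xy(p))
    return int(i)


def lane_position(p, track: TrackGeometry) -> float:
    """Signed lateral distance from the reference line.

    Positive values point toward the outer edge of the current curve; on
    straight segments positive means right of the centerline.
    """
    i = _closest_station(p, track)
    t = track.tangent_at_index(i)
    right = np.array([t[1], -t[0]])  # right-hand normal of the tangent
    raw = float(np.dot(_as_xy(p) - track.reference_xy[i], right))
    sign = int(track.curve_signs[i])
    if sign == 0:
        return raw
    # Right turn: center of curvature on the right, outer edge on the left.
    return -sign * raw


def offtrack(p, track: TrackGeometry) -> bool:
    """True iff the point lies beyond the track edges."""
    return abs(lane_position(p, track)) > track.half_width


def mean_reference_path(
    trials: Sequence, base_track: TrackGeometry, spacing: float = INDEX_SPACING
) -> TrackGeometry:
    """Empirical reference line: the mean trajectory across trials.

    Each trial (a pose series or an (N, 2) position array) contributes, at
    every station of ``base_track``, its position of closest approach to
    that station; stations are averaged across trials and the resulting
    polyline is re-indexed at ``spacing``.
    """
    if len(trials) == 0:
        raise CoverageError("need at least one trial")
    lo, hi = base_track.analysis_window
    stations = base_track.reference_xy
    acc = np.zeros_like(stations)
    for n, trial in enumerate(trials):
        pts = _trial_positions(trial)
        s_proj = closest_track_indices(pts, base_track)
        # one frame of travel at typical speeds may be missing at either end
        tol = max(spacing, 0.3)
        if s_proj.min() > lo + tol or s_proj.max() < hi - tol:
            raise CoverageError(f"trial {n} does not cover the analysis window")
        tree = cKDTree(pts)
        _, nearest = tree.query(stations)
        acc += pts[nearest]
    mean_line = acc / len(trials)

    seg = np.hypot(*np.diff(mean_line, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    grid = _station_grid(cum[-1], spacing)
    xy = np.column_stack(
        [np.interp(grid, cum, mean_line[:, 0]), np.interp(grid, cum, mean_line[:, 1])]
    )
    new = TrackGeometry(
        reference_xy=xy,
        s=grid,
        half_width=base_track.half_width,
        waypoints=base_track.waypoints.copy(),
        waypoint_s=base_track.waypoint_s.copy(),
        curve_signs=np.zeros_like(grid, dtype=int),
        analysis_window=(0.0, float(grid[-1])),
    )
    new.waypoint_s = np.array(
        [closest_track_index(w, new) for w in new.waypoints]
    )
    return new


def _trial_positions(trial) -> np.ndarray:
    if hasattr(trial, "poses"):
        trial = trial.poses
    if len(trial) and isinstance(trial[0], Pose):
        return np.array([[p.x, p.z] for p in trial])
    return np.asarray(trial, dtype=float)
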
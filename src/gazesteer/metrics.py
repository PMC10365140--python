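"""Trajectory-comparison metrics between model and human drives.

Three per-trial metrics: the mean Euclidean distance between the model and
human positions matched by track position (*trajectory error*), the
percentage of frames spent beyond the track edges inside the analysis
window (*offtrack percentage*), and the Pearson correlation of the two
frame-locked yaw-rate series.  Aggregation is always participant-first:
trial metrics are averaged within each participant and the participant
means averaged unweighted (the *grand mean*); correlations are averaged on
the Fisher-z scale and back-transformed.  Landmark trajectory correlations
compare, per participant and landmark, the human and model lane positions
across trials at fixed track stations (e.g., where the reference line
passes each waypoint).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .errors import NoOverlapError
from .sim import SimulationResult, Trial
from .tracks import TrackGeometry, closest_track_indices, lane_position

#: |z| cap applied before averaging so r = +/-1 stays finite.
_Z_CAP = math.atanh(1.0 - 1e-12)


@dataclass
class MetricsSummary:
    """Table-shaped summary of one model variant over a dataset."""

    model: str
    per_participant: pd.DataFrame      # mean_error, offtrack_pct, yawrate_r
    grand_mean_error: float
    mean_offtrack_pct: float
    mean_yawrate_r: float
    landmark_correlations: dict[str, float]


def _resample_on_track(
    positions: np.ndarray, s_series: np.ndarray, stations_xy: np.ndarray
) -> np.ndarray:
    """Trajectory position of closest approach to each reference station."""
    tree = cKDTree(positions)
    _, nearest = tree.query(stations_xy)
    return positions[nearest]


def _coverage(s_series: np.ndarray) -> tuple[float, float]:
    return float(np.min(s_series)), float(np.max(s_series))


def trajectory_error(
    model: SimulationResult, human: Trial, track: TrackGeometry | None = None
) -> float:
    """Mean distance between model and human positions by track position.

    Both trajectories are resampled onto the reference-line stations they
    jointly cover (restricted to the analysis window): at each station the
    position of closest approach is taken, and the mean Euclidean distance
    between the paired positions is returned.
    """
    track = track or human.track
    h_pos = np.array([[p.x, p.z] for p in human.poses])
    m_pos = model.positions
    if len(h_pos) == 0 or len(m_pos) == 0:
        raise NoOverlapError("empty trajectory")
    h_s = closest_track_indices(h_pos, track)
    lo = max(_coverage(model.s_track)[0], _coverage(h_s)[0], track.analysis_window[0])
    hi = min(_coverage(model.s_track)[1], _coverage(h_s)[1], track.analysis_window[1])
    if hi <= lo:
        raise NoOverlapError("trajectories share no arc-length interval")
    mask = (track.s >= lo) & (track.s <= hi)
    stations = track.reference_xy[mask]
    m_r = _resample_on_track(m_pos, model.s_track, stations)
    h_r = _resample_on_track(h_pos, h_s, stations)
    return float(np.mean(np.hypot(*(m_r - h_r).T)))


def offtrack_percentage(
    model: SimulationResult, window: tuple[float, float] | None = None
) -> float:
    """Percent of frames beyond the track edges within the analysis window."""
    window = window or model.source.track.analysis_window
    mask = (model.s_track >= window[0]) & (model.s_track <= window[1])
    n = int(mask.sum())
    if n == 0:
        return 0.0
    return 100.0 * float(model.offtrack_flags[mask].sum()) / n


def yawrate_correlation(model: SimulationResult, human: Trial) -> float:
    """Pearson r between frame-locked model and human yaw-rate series.

    Returns NaN (flagged, excluded from averages) when either series has
    zero variance.
    """
    m = model.yaw_rates
    h = np.array([p.yaw_rate for p in human.poses])
    if len(m) != len(h):
        raise NoOverlapError("yaw-rate series lengths differ")
    if np.std(m) == 0.0 or np.std(h) == 0.0:
        warnings.warn("zero-variance yaw-rate series; correlation undefined")
        return math.nan
    return float(pearsonr(m, h).statistic)


def fisher_mean(rs) -> float:
    """Fisher-z average of correlations, back-transformed; NaNs excluded."""
    rs = np.asarray(rs, dtype=float)
    rs = rs[~np.isnan(rs)]
    if len(rs) == 0:
        return math.nan
    z = np.arctanh(np.clip(rs, -(1.0 - 1e-12), 1.0 - 1e-12))
    return float(np.tanh(np.mean(z)))


def _lane_at_station(
    positions: np.ndarray, s_series: np.ndarray, s_landmark: float, track: TrackGeometry
) -> float:
    """Lane position at the frame of closest approach to a track station."""
    i = int(np.argmin(np.abs(s_series - s_landmark)))
    return lane_position(positions[i], track)


def landmark_trajectory_correlation(
    models: list[SimulationResult],
    humans: list[Trial],
    landmarks: dict[str, float],
    track: TrackGeometry | None = None,
) -> dict[str, float]:
    """Across-trial human/model lane-position correlations at fixed stations.

    For each participant and landmark station, the Pearson r across that
    participant's trials between human and model lane positions when
    passing the station; returned per landmark as the back-transformed mean
    of the participant-wise Fisher-z values.  Zero-variance participants
    are dropped with a warning.
    """
    track = track or humans[0].track
    by_participant: dict[str, list[tuple[SimulationResult, Trial]]] = {}
    for m, h in zip(models, humans):
        by_participant.setdefault(h.participant_id, []).append((m, h))

    out: dict[str, float] = {}
    for name, s_lm in landmarks.items():
        zs = []
        for pid, pairs in by_participant.items():
            hv, mv = [], []
            for m, h in pairs:
                h_pos = np.array([[p.x, p.z] for p in h.poses])
                h_s = closest_track_indices(h_pos, track)
                hv.append(_lane_at_station(h_pos, h_s, s_lm, track))
                mv.append(_lane_at_station(m.positions, m.s_track, s_lm, track))
            if len(hv) < 3:
                continue
            if np.std(hv) == 0.0 or np.std(mv) == 0.0:
                warnings.warn(
                    f"participant {pid}: zero variance at landmark {name}; dropped"
                )
                continue
            r = float(pearsonr(hv, mv).statistic)
            zs.append(r)
        out[name] = fisher_mean(zs)
    return out


def summarize(
    models: list[SimulationResult],
    humans: list[Trial],
    landmarks: dict[str, float] | None = None,
    track: TrackGeometry | None = None,
) -> MetricsSummary:
    """Participant-first aggregation of all per-trial metrics."""
    track = track or humans[0].track
    rows = []
    for m, h in zip(models, humans):
        rows.append(
            {
                "participant_id": h.participant_id,
                "trial_id": h.trial_id,
                "error_m": trajectory_error(m, h, track),
                "offtrack_pct": offtrack_percentage(m),
                "yawrate_r": yawrate_correlation(m, h),
            }
        )
    per_trial = pd.DataFrame(rows)
    per_participant = per_trial.groupby("participant_id").agg(
        mean_error=("error_m", "mean"),
        offtrack_pct=("offtrack_pct", "mean"),
        yawrate_r=("yawrate_r", fisher_mean),
    )
    lm = (
        landmark_trajectory_correlation(models, humans, landmarks, track)
        if landmarks
        else {}
    )
    return MetricsSummary(
        model=models[0].model if models else "",
        per_participant=per_participant,
        grand_mean_error=float(per_participant["mean_error"].mean()),
        mean_offtrack_pct=float(per_participant["offtrack_pct"].mean()),
        mean_yawrate_r=fisher_mean(per_participant["yawrate_r"].to_numpy()),
        landmark_correlations=lm,
    )
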
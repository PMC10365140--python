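"""File formats, run configuration, and the end-to-end experiment driver.

Time series travel as headered CSV (angles in degrees at the file
boundary, radians in memory), tracks as JSON parameter records that are
rebuilt by the geometry constructors, and controller parameters as flat
TOML.  ``run_experiment`` ties the pipeline together: load (or generate) a
dataset, apply the gaze-quality trial exclusion, run the requested
controller x input variants over every trial, and write per-trial results
plus a summary table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .controllers import (
    CONTROLLERS,
    PROPORTIONAL,
    PURE_PURSUIT,
    YAW_LIMIT_SLALOM,
    ControllerParams,
)
from .errors import ConfigError, SchemaError
from .gaze import GazeRecord, exclude_trial
from .metrics import MetricsSummary, summarize
from .sim import GAZE, INPUT_MODES, WAYPOINTS, SimulationResult, Trial, run_trial
from .synth import SPEED_SBEND, SPEED_SLALOM, default_config, generate_dataset
from .tracks import (
    Pose,
    TrackGeometry,
    build_sbend_track,
    build_slalom_track,
)

log = logging.getLogger(__name__)

#: Reference fitted parameter values shipped with the package, keyed by
#: (input_mode, controller): gain k, smoothing a, and waypoint-switch th.
REFERENCE_PARAMS: dict[tuple[str, str], dict[str, float]] = {
    (GAZE, PURE_PURSUIT): {"k": 1.24, "a": 0.06},
    (GAZE, PROPORTIONAL): {"k": 2.23, "a": 0.06},
    (WAYPOINTS, PURE_PURSUIT): {"k": 1.25, "a": 0.06, "th": 0.59},
    (WAYPOINTS, PROPORTIONAL): {"k": 2.83, "a": 0.16, "th": 0.25},
}


def reference_params(
    input_mode: str, controller: str, experiment: str = "exp1"
) -> ControllerParams:
    """Shipped fitted parameters for one model variant and configuration."""
    try:
        base = REFERENCE_PARAMS[(input_mode, controller)]
    except KeyError as exc:
        raise ConfigError(f"unknown variant {input_mode}+{controller}") from exc
    v = SPEED_SLALOM if experiment == "exp1" else SPEED_SBEND
    yaw_limit = YAW_LIMIT_SLALOM if experiment == "exp1" else None
    return ControllerParams(v=v, yaw_limit=yaw_limit, **base)


# ---------------------------------------------------------------------------
# Trial / gaze CSV

_TRIAL_COLUMNS = ["t", "x", "z", "heading_deg", "yaw_rate_deg"]
_GAZE_COLUMNS = ["t", "s_human", "fixation_x", "fixation_z", "elevation_deg"]


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")


def write_trial(trial: Trial, path) -> None:
    """Pose series to CSV with metadata comment lines (degrees at boundary)."""
    path = Path(path)
    n = len(trial.poses)
    dt = 1.0 / 60.0
    df = pd.DataFrame(
        {
            "t": np.arange(n) * dt,
            "x": [p.x for p in trial.poses],
            "z": [p.z for p in trial.poses],
            "heading_deg": [np.degrees(p.heading) for p in trial.poses],
            "yaw_rate_deg": [np.degrees(p.yaw_rate) for p in trial.poses],
        }
    )
    header = (
        f"# participant_id={trial.participant_id}\n"
        f"# trial_id={trial.trial_id}\n"
        f"# experiment={trial.experiment}\n"
        f"# v={'' if trial.v is None else repr(trial.v)}\n"
        "# units: t s, x/z m, heading/yaw_rate deg\n"
    )
    with open(path, "w") as f:
        f.write(header)
        df.to_csv(f, index=False)


def _read_meta(path) -> dict[str, str]:
    meta = {}
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


def read_trial(path, track: TrackGeometry, gaze: list[GazeRecord] | None = None) -> Trial:
    """Trial CSV back to in-memory poses (radians); validates the schema."""
    path = Path(path)
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    _check_columns(df, _TRIAL_COLUMNS, path)
    t = df["t"].to_numpy(float)
    if len(t) > 1:
        dts = np.diff(t)
        if np.any(dts <= 0):
            raise SchemaError(f"{path}: non-monotonic time column")
        if abs(np.median(dts) - 1.0 / 60.0) > 0.01 / 60.0:
            log.warning("%s: median frame period deviates >1%% from 60 Hz", path)
    poses = [
        Pose(
            x=row.x,
            z=row.z,
            heading=np.radians(row.heading_deg),
            yaw_rate=np.radians(row.yaw_rate_deg),
        )
        for row in df.itertuples()
    ]
    v = meta.get("v") or None
    return Trial(
        participant_id=meta.get("participant_id", "unknown"),
        trial_id=meta.get("trial_id", "0"),
        experiment=meta.get("experiment", "exp1"),
        poses=poses,
        gaze=gaze or [],
        track=track,
        v=float(v) if v else None,
    )


def write_gaze(records: list[GazeRecord], path) -> None:
    """Gaze records to CSV (world fixation coordinates, elevation in deg)."""
    df = pd.DataFrame(
        {
            "t": [r.t for r in records],
            "s_human": [r.s_human for r in records],
            "fixation_x": [r.fixation_x for r in records],
            "fixation_z": [r.fixation_z for r in records],
            "elevation_deg": [r.elevation for r in records],
        }
    )
    with open(path, "w") as f:
        f.write("# units: t s, s_human/fixation m, elevation deg (neg = below horizon)\n")
        df.to_csv(f, index=False)


def read_gaze(path, poses: list[Pose] | None = None) -> list[GazeRecord]:
    """Gaze CSV back to records.

    Accepts either the fixation-coordinate layout or the raw-angle layout
    (``azimuth_deg``/``elevation_deg``); the latter needs the frame-aligned
    pose series to project angles onto the ground plane.
    """
    from .gaze import fixation_from_gaze_angles

    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if "azimuth_deg" in df.columns:
        _check_columns(df, ["t", "s_human", "azimuth_deg", "elevation_deg"], path)
        if poses is None or len(poses) < len(df):
            raise SchemaError(f"{path}: angle layout requires an aligned pose series")
        return [
            fixation_from_gaze_angles(
                poses[i], row.azimuth_deg, row.elevation_deg,
                t=row.t, s_human=row.s_human,
            )
            for i, row in enumerate(df.itertuples())
        ]
    _check_columns(df, _GAZE_COLUMNS, path)
    return [
        GazeRecord(
            t=row.t,
            s_human=row.s_human,
            fixation_x=row.fixation_x,
            fixation_z=row.fixation_z,
            elevation=row.elevation_deg,
            valid=bool(np.isfinite(row.fixation_x)) and row.elevation_deg < 0,
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Track JSON + reference-line CSV

_TRACK_BUILDERS = {"slalom": build_slalom_track, "sbend": build_sbend_track}


def write_track(track_type: str, parameters: dict, path) -> None:
    if track_type not in _TRACK_BUILDERS:
        raise SchemaError(f"unknown track type {track_type!r}")
    Path(path).write_text(
        json.dumps({"type": track_type, "parameters": parameters}, indent=2)
    )


def read_track(path) -> TrackGeometry:
    spec = json.loads(Path(path).read_text())
    try:
        builder = _TRACK_BUILDERS[spec["type"]]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: missing or unknown track type") from exc
    return builder(**spec.get("parameters", {}))


def write_reference_line(track: TrackGeometry, path) -> None:
    pd.DataFrame(
        {
            "s": track.s,
            "x": track.reference_xy[:, 0],
            "z": track.reference_xy[:, 1],
            "curve_sign": track.curve_signs,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Parameter TOML

def write_params(params: ControllerParams, path) -> None:
    lines = []
    for f in dataclasses.fields(params):
        val = getattr(params, f.name)
        if val is None:
            continue
        lines.append(f"{f.name} = {val!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path) -> ControllerParams:
    data = tomllib.loads(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(ControllerParams)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"{path}: unknown parameter keys {sorted(unknown)}")
    return ControllerParams(**data)


# ---------------------------------------------------------------------------
# Dataset directory layout

def write_dataset(trials: list[Trial], track_type: str, track_params: dict, out_dir) -> None:
    """Standard layout: out/track.json + out/<participant>/trial_<id>.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_track(track_type, track_params, out / "track.json")
    for trial in trials:
        pdir = out / trial.participant_id
        pdir.mkdir(exist_ok=True)
        write_trial(trial, pdir / f"trial_{trial.trial_id}.csv")
        write_gaze(trial.gaze, pdir / f"trial_{trial.trial_id}_gaze.csv")


def read_dataset(in_dir) -> list[Trial]:
    root = Path(in_dir)
    track = read_track(root / "track.json")
    trials = []
    for pdir in sorted(p for p in root.iterdir() if p.is_dir()):
        for tfile in sorted(pdir.glob("trial_*.csv")):
            if tfile.stem.endswith("_gaze"):
                continue
            gfile = pdir / f"{tfile.stem}_gaze.csv"
            gaze = read_gaze(gfile) if gfile.exists() else []
            trials.append(read_trial(tfile, track, gaze))
    return trials


# ---------------------------------------------------------------------------
# Run configuration and the end-to-end driver

@dataclass
class RunConfig:
    """End-to-end run description (strict: unknown keys are rejected)."""

    experiment: str = "exp1"
    controllers: tuple[str, ...] = CONTROLLERS
    input_modes: tuple[str, ...] = INPUT_MODES
    dataset_dir: str | None = None       # None -> generate synthetically
    out_dir: str | None = None
    seed: int = 0
    trials_per_participant: int = 3
    n_participants: int | None = None
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2"):
            raise ConfigError(f"unknown experiment {self.experiment!r}")
        for c in self.controllers:
            if c not in CONTROLLERS:
                raise ConfigError(f"unknown controller {c!r}")
        for m in self.input_modes:
            if m not in INPUT_MODES:
                raise ConfigError(f"unknown input mode {m!r}")
        if self.dataset_dir is not None and not Path(self.dataset_dir).exists():
            raise ConfigError(f"dataset dir {self.dataset_dir} does not exist")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        for key in ("controllers", "input_modes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _landmarks(track: TrackGeometry, experiment: str) -> dict[str, float]:
    if experiment == "exp1":
        return {f"WP{i + 1}": float(s) for i, s in enumerate(track.waypoint_s)}
    lo, hi = track.analysis_window
    return {"Beginning": lo, "Middle": 0.5 * (lo + hi), "End": hi}


def run_experiment(config: RunConfig) -> dict[str, MetricsSummary]:
    """Load or generate a dataset, run every requested variant, summarize.

    Trials failing the gaze-quality exclusion are dropped (and logged) for
    gaze-input variants; waypoint variants run on all trials.  Returns one
    summary per "controller+input" tag; writes CSV output when an output
    directory is configured.
    """
    if config.dataset_dir is not None:
        trials = read_dataset(config.dataset_dir)
    else:
        cfg = default_config(
            config.experiment,
            seed=config.seed,
            trials_per_participant=config.trials_per_participant,
            n_participants=config.n_participants,
        )
        trials = generate_dataset(config.experiment, cfg)
    if not trials:
        raise ConfigError("dataset is empty")
    track = trials[0].track

    kept = []
    for trial in trials:
        if trial.gaze and exclude_trial(trial.gaze):
            log.info(
                "excluding trial %s/%s: >10%% of gaze samples above -2 deg",
                trial.participant_id, trial.trial_id,
            )
            continue
        kept.append(trial)

    landmarks = _landmarks(track, config.experiment)
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    summaries: dict[str, MetricsSummary] = {}
    rows = []
    for mode in config.input_modes:
        eligible = kept if mode == GAZE else trials
        eligible = [t for t in eligible if len(t.poses) > 0]
        for controller in config.controllers:
            params = reference_params(mode, controller, config.experiment)
            results: list[SimulationResult] = []
            humans: list[Trial] = []
            for trial in eligible:
                if mode == GAZE and len(trial.gaze) < 2:
                    continue
                results.append(run_trial(trial, params, controller, mode))
                humans.append(trial)
            summary = summarize(results, humans, landmarks, track)
            tag = f"{controller}+{mode}"
            summaries[tag] = summary
            row = {
                "input": mode,
                "controller": controller,
                "mean_yawrate_r": summary.mean_yawrate_r,
                "grand_mean_error_m": summary.grand_mean_error,
                "mean_offtrack_pct": summary.mean_offtrack_pct,
            }
            row.update(
                {f"traj_r_{k}": v for k, v in summary.landmark_correlations.items()}
            )
            rows.append(row)
            if out:
                summary.per_participant.to_csv(out / f"per_participant_{tag}.csv")
    summary_df = pd.DataFrame(rows)
    if out:
        summary_df.to_csv(out / "summary.csv", index=False)
    return summaries


def summary_table(summaries: dict[str, MetricsSummary]) -> pd.DataFrame:
    """Flat table (one row per model variant) from ``run_experiment`` output."""
    rows = []
    for tag, s in summaries.items():
        controller, mode = tag.split("+")
        row = {
            "input": mode,
            "controller": controller,
            "mean_yawrate_r": s.mean_yawrate_r,
            "grand_mean_error_m": s.grand_mean_error,
            "mean_offtrack_pct": s.mean_offtrack_pct,
        }
        row.update({f"traj_r_{k}": v for k, v in s.landmark_correlations.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_result(result: SimulationResult, path) -> None:
    """Per-frame model output CSV: pose, steering point, track position."""
    n = len(result.poses)
    dt = 1.0 / 60.0
    pd.DataFrame(
        {
            "frame": np.arange(n),
            "t": np.arange(n) * dt,
            "x": [p.x for p in result.poses],
            "z": [p.z for p in result.poses],
            "heading_deg": [np.degrees(p.heading) for p in result.poses],
            "yaw_rate_deg": [np.degrees(p.yaw_rate) for p in result.poses],
            "sp_x_ego": [sp.x_ego for sp in result.steering_points],
            "sp_z_ego": [sp.z_ego for sp in result.steering_points],
            "s_track": result.s_track,
            "offtrack": result.offtrack_flags.astype(int),
        }
    ).to_csv(path, index=False)
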
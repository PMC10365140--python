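"""Controller-parameter fitting: grid search refined by Nelder-Mead.

The objective is the grand mean trajectory error: every trial in the
dataset is simulated with one shared parameter vector, trial errors are
averaged within each participant, and the participant means are averaged
unweighted.  A coarse grid over the admissible box (k in 0.9-3, a in
0.05-1, th in 0.1-0.8 for waypoint input) locates an initial guess; the
Nelder-Mead simplex then refines it.  Proposals outside the box are
clamped back and penalized so the search stays in physically meaningful
territory.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .controllers import ControllerParams
from .errors import GazeSteerError, InvalidParameterError, OptimizationError
from .metrics import trajectory_error
from .sim import WAYPOINTS, Trial, run_trial

log = logging.getLogger(__name__)

#: Objective value assigned to a failed simulation (meters).
FAILURE_PENALTY = 1e3

#: Extra penalty (meters) for out-of-box Nelder-Mead proposals.
CLAMP_PENALTY = 1.0


@dataclass
class SearchSpace:
    """Box constraints and grid resolution of the parameter search."""

    k_range: tuple[float, float] = (0.9, 3.0)
    a_range: tuple[float, float] = (0.05, 1.0)
    th_range: tuple[float, float] = (0.1, 0.8)
    grid_points_per_axis: int = 8

    def __post_init__(self) -> None:
        for lo, hi in (self.k_range, self.a_range, self.th_range):
            if not 0 < lo < hi:
                raise InvalidParameterError("ranges must be ordered and positive")
        if self.grid_points_per_axis < 2:
            raise InvalidParameterError("need >= 2 grid points per axis")

    def axes(self, with_th: bool) -> list[np.ndarray]:
        n = self.grid_points_per_axis
        axes = [np.linspace(*self.k_range, n), np.linspace(*self.a_range, n)]
        if with_th:
            axes.append(np.linspace(*self.th_range, n))
        return axes

    def clamp(self, theta: np.ndarray, with_th: bool) -> tuple[np.ndarray, bool]:
        boxes = [self.k_range, self.a_range] + ([self.th_range] if with_th else [])
        clamped = np.array(
            [min(max(t, lo), hi) for t, (lo, hi) in zip(theta, boxes)]
        )
        return clamped, bool(np.any(clamped != theta))


@dataclass
class FitResult:
    """Fitted parameters plus the full evaluation trace."""

    params: ControllerParams
    objective: float
    trace: pd.DataFrame = field(repr=False)


def objective(
    params: ControllerParams,
    dataset: list[Trial],
    controller: str,
    input_mode: str,
) -> float:
    """Grand mean trajectory error of one parameter vector over a dataset.

    Simulation failures contribute a large finite penalty so the optimizer
    can keep moving.
    """
    if not dataset:
        raise InvalidParameterError("empty dataset")
    per_participant: dict[str, list[float]] = {}
    for trial in dataset:
        try:
            result = run_trial(trial, params, controller, input_mode)
            err = trajectory_error(result, trial)
        except GazeSteerError as exc:
            log.warning(
                "trial %s/%s failed under %s+%s: %s",
                trial.participant_id, trial.trial_id, controller, input_mode, exc,
            )
            err = FAILURE_PENALTY
        per_participant.setdefault(trial.participant_id, []).append(err)
    return float(np.mean([np.mean(v) for v in per_participant.values()]))


def fit_parameters(
    dataset: list[Trial],
    controller: str,
    input_mode: str,
    space: SearchSpace | None = None,
    base_params: ControllerParams | None = None,
    seed: int | None = None,
    xatol: float = 1e-3,
    fatol: float = 1e-3,
    maxiter: int = 200,
    objective_fn=None,
) -> FitResult:
    """Grid search, then Nelder-Mead from the grid argmin.

    ``base_params`` supplies the fixed quantities (speed, dt, yaw limit);
    defaults to the first trial's nominal speed.  ``seed`` is accepted for
    interface symmetry — the procedure itself is deterministic.
    ``objective_fn`` (params -> meters) replaces the dataset objective,
    e.g. for analytic checks of the search machinery.
    """
    space = space or SearchSpace()
    with_th = input_mode == WAYPOINTS
    if base_params is None:
        v = dataset[0].v if dataset else 1.0
        if v is None:
            raise InvalidParameterError("dataset has no nominal speed; pass base_params")
        base_params = ControllerParams(k=1.0, a=1.0, v=v, th=0.5 if with_th else None)
    if objective_fn is None:
        def objective_fn(params):
            return objective(params, dataset, controller, input_mode)

    def make(theta: np.ndarray) -> ControllerParams:
        kw = {"k": float(theta[0]), "a": float(theta[1])}
        if with_th:
            kw["th"] = float(theta[2])
        return replace(base_params, **kw)

    rows = []
    best_theta, best_val = None, np.inf
    for theta in itertools.product(*space.axes(with_th)):
        theta = np.array(theta)
        val = objective_fn(make(theta))
        rows.append({"stage": "grid", "k": theta[0], "a": theta[1],
                     "th": theta[2] if with_th else np.nan, "objective": val})
        if val < best_val:
            best_theta, best_val = theta, val
    if best_theta is None or best_val >= FAILURE_PENALTY:
        raise OptimizationError("every grid point failed to simulate")

    def penalized(theta: np.ndarray) -> float:
        clamped, was_out = space.clamp(theta, with_th)
        val = objective_fn(make(clamped))
        if was_out:
            val += CLAMP_PENALTY
        rows.append({"stage": "nelder-mead", "k": clamped[0], "a": clamped[1],
                     "th": clamped[2] if with_th else np.nan, "objective": val})
        return val

    res = minimize(
        penalized,
        best_theta,
        method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter},
    )
    theta_final, _ = space.clamp(res.x, with_th)
    final_val = objective_fn(make(theta_final))
    if final_val > best_val:  # refinement never worsens the grid argmin
        theta_final, final_val = best_theta, best_val
    return FitResult(make(theta_final), final_val, pd.DataFrame(rows))
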
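"""Levenberg-Marquardt calibration of the four global model parameters.

Given a degraded time course (day-1 fields plus at least one later imaging
day), the calibrator estimates (D_t0, D_v0, k_t, k_v) by damped
Gauss-Newton least squares: the model is forward-simulated from the
observed day-1 fields with candidate parameters, voxelwise residuals
(model - observed) for both species at every later observed day are
stacked into one vector, and a finite-difference Jacobian over the four
parameters drives the LM update. The calibrated parameters are then used to
simulate forward to the prediction horizon (day 10).

The observed day-1 fields — noisy as they are — serve as the initial
condition; the calibrator never sees clean data. Parameters are bounded to
a physical, numerically stable region; trial points are projected onto the
bounds. By default both species carry equal per-voxel weight, which lets
the larger-magnitude tumor residuals dominate the objective (an optional
species weighting is exposed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

from .cohort import ModelParameters, CALIBRATED_NAMES
from .domain import TissueDomain
from .growth import SolverConfig, TimeCourse, simulate

__all__ = ["CalibrationConfig", "CalibrationResult", "residuals", "calibrate", "predict"]

_PENALTY = 1.0e6


@dataclass(frozen=True)
class CalibrationConfig:
    """Optimizer settings.

    ``lower``/``upper`` bound (D_t0, D_v0, k_t, k_v); diffusivities are kept
    below 0.1 mm^2/day so the explicit forward solver remains stable at
    dt = 0.01 on the study grids. The initial guess is the truth perturbed
    by a seeded uniform +/-``guess_spread`` per parameter when
    ``true_parameters`` is provided (experiment mode), else the central
    literature values.
    """

    lower: Tuple[float, float, float, float] = (1e-6, 1e-6, 1e-3, 1e-3)
    upper: Tuple[float, float, float, float] = (0.1, 0.1, 5.0, 5.0)
    max_iterations: int = 50
    ftol: float = 1e-6
    xtol: float = 1e-8
    fd_rel_step: float = 1e-3
    lm_lambda0: float = 1e-3
    jacobian_refresh: int = 1  # recompute the FD Jacobian every n-th accepted step
    tumor_weight: float = 1.0
    vasc_weight: float = 1.0
    true_parameters: ModelParameters | None = None
    guess_spread: float = 0.5
    solver: SolverConfig = field(default_factory=SolverConfig)


@dataclass
class CalibrationResult:
    """Estimated parameters plus the optimizer trace."""

    estimated: ModelParameters
    initial_guess: ModelParameters
    objective_trace: list[float]
    converged: bool
    n_iterations: int
    condition: object | None = None

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]


def _observed_arrays(observed: TimeCourse):
    days = observed.days
    if len(days) < 2:
        raise ValueError("observed time course needs the day-1 initial condition "
                         "plus at least one later day")
    first = days[0]
    later = days[1:]
    return first, later


def residuals(
    params_vec: Sequence[float],
    observed: TimeCourse,
    fixed: ModelParameters,
    domain: TissueDomain,
    config: CalibrationConfig | None = None,
) -> np.ndarray:
    """Stacked voxelwise residuals (model - observed) for a candidate vector.

    Simulates forward from the observed first-day fields with the candidate
    (D_t0, D_v0, k_t, k_v) grafted onto ``fixed``, and concatenates the
    weighted differences for N_t then N_v at every later observed day. A
    forward-model failure (instability, solver breakdown) returns a
    constant large-penalty vector of the same length so the optimizer
    retreats from that region.
    """
    if config is None:
        config = CalibrationConfig()
    first, later = _observed_arrays(observed)
    n_vox = int(np.prod(observed.grid.shape))
    n_res = len(later) * 2 * n_vox
    params = fixed.with_calibrated(params_vec)
    try:
        course = simulate(
            (observed.tumor(first), observed.vasculature(first)),
            params,
            domain,
            days=later[-1] - first + 1,
            config=config.solver,
        )
    except Exception:
        return np.full(n_res, _PENALTY)
    res = np.empty(n_res)
    pos = 0
    for day in later:
        model_nt, model_nv = course.snapshots[day - first + 1]
        obs_nt, obs_nv = observed.snapshots[day]
        res[pos:pos + n_vox] = config.tumor_weight * (model_nt - obs_nt).ravel()
        pos += n_vox
        res[pos:pos + n_vox] = config.vasc_weight * (model_nv - obs_nv).ravel()
        pos += n_vox
    if not np.all(np.isfinite(res)):
        return np.full(n_res, _PENALTY)
    return res


def _initial_guess(config: CalibrationConfig, seed: int) -> np.ndarray:
    lower = np.asarray(config.lower)
    upper = np.asarray(config.upper)
    if config.true_parameters is not None:
        rng = np.random.default_rng(seed)
        truth = np.asarray(config.true_parameters.calibrated_vector())
        factors = rng.uniform(1.0 - config.guess_spread, 1.0 + config.guess_spread, size=4)
        guess = truth * factors
    else:
        guess = np.asarray(ModelParameters().calibrated_vector())
    return np.clip(guess, lower, upper)


def calibrate(
    observed: TimeCourse,
    fixed: ModelParameters,
    domain: TissueDomain,
    config: CalibrationConfig | None = None,
    seed: int = 0,
) -> CalibrationResult:
    """Estimate (D_t0, D_v0, k_t, k_v) by Levenberg-Marquardt.

    Damped Gauss-Newton with a forward finite-difference Jacobian over the
    four parameters; accepted steps never increase the objective, so the
    trace is non-increasing. Deterministic given the seed and inputs.
    Returns with ``converged=False`` (but with the best parameters found)
    if the iteration budget is exhausted.
    """
    if config is None:
        config = CalibrationConfig()
    lower = np.asarray(config.lower, dtype=float)
    upper = np.asarray(config.upper, dtype=float)
    x = _initial_guess(config, seed)
    guess_params = fixed.with_calibrated(x)

    def cost_and_res(vec):
        r = residuals(vec, observed, fixed, domain, config)
        return float(r @ r), r

    f0, r = cost_and_res(x)
    trace = [f0]
    if config.max_iterations == 0:
        return CalibrationResult(guess_params, guess_params, trace, False, 0)

    def jacobian(x_at, r_at):
        # forward differences, stepping away from the nearer bound
        J = np.empty((r_at.size, 4))
        for p in range(4):
            h = config.fd_rel_step * max(abs(x_at[p]), 1e-8)
            xp = x_at.copy()
            if xp[p] + h > upper[p]:
                h = -h
            xp[p] = np.clip(xp[p] + h, lower[p], upper[p])
            rp = residuals(xp, observed, fixed, domain, config)
            J[:, p] = (rp - r_at) / (xp[p] - x_at[p])
        return J

    lam = config.lm_lambda0
    converged = False
    n_iter = 0
    J = None
    j_age = 0
    refresh = max(1, config.jacobian_refresh)
    for n_iter in range(1, config.max_iterations + 1):
        if J is None or j_age >= refresh:
            J = jacobian(x, r)
            j_age = 0
        g = J.T @ r
        H = J.T @ J
        accepted = False
        for _ in range(10):
            damped = H + lam * np.diag(np.maximum(np.diag(H), 1e-30))
            try:
                delta = np.linalg.solve(damped, -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            x_try = np.clip(x + delta, lower, upper)
            f_try, r_try = cost_and_res(x_try)
            if f_try < f0:
                step_norm = np.linalg.norm(x_try - x)
                rel_drop = (f0 - f_try) / max(f0, 1e-300)
                x, f0, r = x_try, f_try, r_try
                lam = max(lam / 3.0, 1e-12)
                accepted = True
                j_age += 1
                trace.append(f0)
                if rel_drop < config.ftol or step_norm < config.xtol * (1 + np.linalg.norm(x)):
                    converged = True
                break
            lam *= 4.0
        if not accepted:
            if j_age > 0:
                # the reused Jacobian went stale; refresh and retry
                J = None
                continue
            converged = True  # fresh Jacobian yields no descent at any damping
            break
        if converged:
            break
    return CalibrationResult(
        estimated=fixed.with_calibrated(x),
        initial_guess=guess_params,
        objective_trace=trace,
        converged=converged,
        n_iterations=n_iter,
    )


def predict(
    result: CalibrationResult | ModelParameters,
    initial,
    domain: TissueDomain,
    horizon: int = 10,
    solver: SolverConfig | None = None,
) -> TimeCourse:
    """Forward-simulate from day-1 fields with calibrated parameters.

    Snapshots run through all integer days up to ``horizon`` (days 6 and 10
    feed the downstream accuracy metrics).
    """
    params = result.estimated if isinstance(result, CalibrationResult) else result
    return simulate(initial, params, domain, days=horizon,
                    config=solver if solver is not None else SolverConfig())
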
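"""Coupled tumor/vasculature reaction-diffusion growth solver.

Two species evolve on the brain domain: the tumor volume fraction N_t and
the vasculature volume fraction N_v. Each diffuses with a self-diffusion
term weighted by the space left by the other species and a nonlinear
cross-diffusion term driven by the other species' gradient:

    dN_t/dt = div[ D_t ( (1 - N_v/theta) grad N_t + (N_t/theta) grad N_v ) ]
              + k_t N_t (1 - N_t/theta)
    dN_v/dt = div[ D_v ( (1 - N_t/theta) grad N_v + (N_v/theta) grad N_t ) ]
              + k_v N_v (1 - N_v/theta) d(x) - k_dv N_v (1 - d(x))

The shared carrying capacity theta(x, t) rises linearly with the local
vasculature up to theta_max once N_v reaches nv_thresh. Angiogenesis is
gated to the tumor periphery and vessel regression to the core through the
normalized distance-to-periphery map d(x) in [0, 1] (1 at the rim, 0 at the
deepest voxel). Diffusion coefficients are the stress-modulated fields from
:mod:`gliopred.mechanics`.

Discretization: divergence-form fluxes with face-centered coefficients
(arithmetic means of the adjacent voxels), which conserves total mass
discretely under pure diffusion; explicit forward Euler in time with a
pre-run stability audit; zero-flux boundaries at the brain-mask surface so
nothing leaks out of the skull. Fields are clipped voxelwise to
[0, theta] after each step (cross-diffusion can produce small negatives at
steep fronts). The time stepper is compiled with numba; a pure-numpy
reference of the same update is kept for cross-checking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
from numba import njit
from scipy import ndimage

from .grids import Grid, ScalarField, block_mean, resample_to_grid
from .domain import TissueDomain
from .cohort import ModelParameters
from . import mechanics

__all__ = [
    "SolverConfig",
    "SimulationState",
    "TimeCourse",
    "StabilityError",
    "carrying_capacity",
    "distance_to_periphery",
    "max_stable_dt",
    "step",
    "simulate",
]

logger = logging.getLogger(__name__)


class StabilityError(RuntimeError):
    """Raised when the explicit time step violates the diffusion stability bound."""


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings of the forward solver.

    dt
        Forward-Euler step in days (default 0.01).
    mechanics_interval
        Days between mechanical equilibrium solves; the stress field (and
        hence the diffusion fields) is held fixed in between. Default 1.0
        (one solve per simulated day).
    d_update_interval
        Days between recomputations of the distance-to-periphery map;
        None recomputes every step.
    tumor_mask_factor
        The tumor mask used for d(x) is N_t > tumor_mask_factor * theta_max.
    stability_check
        Audit the stability bound before running and raise on violation.
    mechanics_coarsen
        Grid-coarsening factor for the mechanical equilibrium solve: 1 solves
        on the simulation grid; 0 (auto) coarsens by powers of two while the
        grid exceeds ~6000 voxels, then interpolates the smooth von Mises
        field back. Direct sparse factorization of the elasticity system
        scales badly with grid size, and the stress field varies on the
        lesion scale, so the coarse solve changes the diffusion modulation
        only marginally.
    """

    dt: float = 0.01
    mechanics_interval: float = 1.0
    d_update_interval: float | None = None
    tumor_mask_factor: float = 0.05
    stability_check: bool = True
    mechanics_coarsen: int = 0


@dataclass
class SimulationState:
    """Instantaneous solver state: fields and their derived maps at time t (days)."""

    t: float
    grid: Grid
    n_t: np.ndarray
    n_v: np.ndarray
    theta: np.ndarray
    d: np.ndarray
    d_t: np.ndarray
    d_v: np.ndarray
    mask: np.ndarray


@dataclass
class TimeCourse:
    """Daily snapshots of (N_t, N_v) on one grid.

    ``snapshots`` maps integer day -> (n_t, n_v) value arrays; days are
    contiguous from the first recorded day (day 1 is the initial condition).
    """

    grid: Grid
    snapshots: Dict[int, Tuple[np.ndarray, np.ndarray]]
    parameters: ModelParameters | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        days = self.days
        if days and days != list(range(days[0], days[0] + len(days))):
            # subsets produced by timepoint selection are allowed to be sparse
            self.metadata.setdefault("sparse_days", True)

    @property
    def days(self) -> list[int]:
        return sorted(self.snapshots)

    def tumor(self, day: int) -> ScalarField:
        return ScalarField(self.grid, self.snapshots[day][0], "tumor_fraction")

    def vasculature(self, day: int) -> ScalarField:
        return ScalarField(self.grid, self.snapshots[day][1], "vasculature_fraction")


def carrying_capacity(
    n_v: np.ndarray | ScalarField,
    theta_min: float = 0.1,
    theta_max: float = 0.9716,
    nv_thresh: float = 0.022,
) -> np.ndarray:
    """Vasculature-dependent carrying capacity theta(x).

    Rises linearly from theta_min at N_v = 0 to theta_max at
    N_v = nv_thresh and saturates there; continuous at the threshold.
    """
    nv = n_v.values if isinstance(n_v, ScalarField) else np.asarray(n_v)
    linear = theta_min + np.minimum(nv, nv_thresh) * (theta_max - theta_min) / nv_thresh
    return np.where(nv >= nv_thresh, theta_max, linear)


def distance_to_periphery(
    n_t: ScalarField | np.ndarray,
    tumor_threshold: float,
    spacing: Sequence[float] | None = None,
) -> np.ndarray:
    """Normalized distance-to-periphery map d(x) in [0, 1].

    The tumor mask is N_t > tumor_threshold. Periphery voxels are mask
    voxels with at least one 6-neighbor inside the box but outside the mask
    (the box edge itself is not periphery, mirroring the zero-flux
    boundary); their d is 1. Deeper voxels take d = 1 - depth / max_depth
    where depth is the Euclidean distance in mm to the nearest periphery
    voxel, so the deepest voxel has d = 0. Outside the mask d = 1. An empty
    mask yields d = 1 everywhere (no tumor, no regression zone).
    """
    if isinstance(n_t, ScalarField):
        values = n_t.values
        spacing = n_t.grid.spacing
    else:
        values = np.asarray(n_t)
        if spacing is None:
            spacing = (1.0, 1.0, 1.0)
    mask = values > tumor_threshold
    d = np.ones(values.shape)
    if not mask.any():
        logger.debug("distance_to_periphery: empty tumor mask, returning d == 1")
        return d
    padded = np.pad(mask, 1, mode="edge")
    interior = padded[1:-1, 1:-1, 1:-1].copy()
    for axis in range(3):
        for shift in (1, -1):
            interior &= np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
    boundary = mask & ~interior
    if not boundary.any():  # mask fills the whole box: no periphery exists
        return d
    depth = ndimage.distance_transform_edt(~boundary, sampling=spacing)
    max_depth = depth[mask].max()
    if max_depth > 0:
        d[mask] = 1.0 - depth[mask] / max_depth
    else:
        d[mask] = 1.0
    return d


def max_stable_dt(d_t_max: float, d_v_max: float, spacing: Sequence[float]) -> float:
    """Largest explicit-Euler step (days) safe for the given diffusivities.

    Uses the classical bound dt <= 1 / (2 D sum(1/h_a^2)) with the two
    species' coefficients summed, which also covers the cross-diffusion
    fluxes (their mobility weights are bounded by 1).
    """
    total = d_t_max + d_v_max
    if total <= 0:
        return np.inf
    inv = sum(1.0 / h**2 for h in spacing)
    return 1.0 / (2.0 * total * inv)


_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=np.int64
)


@njit(cache=True)
def _euler_step_kernel(nt, nv, theta, d, dt_field, dv_field, mask, kt, kv, kdv,
                       dt, inv_h2, offsets, out_nt, out_nv):  # pragma: no cover - compiled
    nx, ny, nz = nt.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    out_nt[i, j, k] = 0.0
                    out_nv[i, j, k] = 0.0
                    continue
                th_p = theta[i, j, k]
                nt_p = nt[i, j, k]
                nv_p = nv[i, j, k]
                wt_self_p = 1.0 - nv_p / th_p
                wt_cross_p = nt_p / th_p
                wv_self_p = 1.0 - nt_p / th_p
                wv_cross_p = nv_p / th_p
                div_t = 0.0
                div_v = 0.0
                for m in range(6):
                    ii = i + offsets[m, 0]
                    jj = j + offsets[m, 1]
                    kk = k + offsets[m, 2]
                    if ii < 0 or ii >= nx or jj < 0 or jj >= ny or kk < 0 or kk >= nz:
                        continue
                    if not mask[ii, jj, kk]:
                        continue
                    th_q = theta[ii, jj, kk]
                    nt_q = nt[ii, jj, kk]
                    nv_q = nv[ii, jj, kk]
                    ih2 = inv_h2[m // 2]
                    dtf = 0.5 * (dt_field[i, j, k] + dt_field[ii, jj, kk])
                    dvf = 0.5 * (dv_field[i, j, k] + dv_field[ii, jj, kk])
                    wt_self = 0.5 * (wt_self_p + (1.0 - nv_q / th_q))
                    wt_cross = 0.5 * (wt_cross_p + nt_q / th_q)
                    wv_self = 0.5 * (wv_self_p + (1.0 - nt_q / th_q))
                    wv_cross = 0.5 * (wv_cross_p + nv_q / th_q)
                    div_t += dtf * (wt_self * (nt_q - nt_p) + wt_cross * (nv_q - nv_p)) * ih2
                    div_v += dvf * (wv_self * (nv_q - nv_p) + wv_cross * (nt_q - nt_p)) * ih2
                dp = d[i, j, k]
                react_t = kt * nt_p * (1.0 - nt_p / th_p)
                react_v = kv * nv_p * (1.0 - nv_p / th_p) * dp - kdv * nv_p * (1.0 - dp)
                nt_new = nt_p + dt * (div_t + react_t)
                nv_new = nv_p + dt * (div_v + react_v)
                if nt_new < 0.0:
                    nt_new = 0.0
                elif nt_new > th_p:
                    nt_new = th_p
                if nv_new < 0.0:
                    nv_new = 0.0
                elif nv_new > th_p:
                    nv_new = th_p
                out_nt[i, j, k] = nt_new
                out_nv[i, j, k] = nv_new


@njit(cache=True)
def _euler_multistep_kernel(nt, nv, d, dt_field, dv_field, mask, kt, kv, kdv,
                            th_min, th_max, nv_th, dt, inv_h2, offsets, n_steps,
                            theta, wts, wtc, wvs, wvc, buf_nt, buf_nv):  # pragma: no cover
    """Run ``n_steps`` Euler updates with fixed d and diffusion fields.

    The carrying capacity and the mobility weights are recomputed inline
    each step; on exit the input ``nt``/``nv`` arrays hold the result."""
    nx, ny, nz = nt.shape
    slope = (th_max - th_min) / nv_th
    for _ in range(n_steps):
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if not mask[i, j, k]:
                        continue
                    nvv = nv[i, j, k]
                    th = th_max if nvv >= nv_th else th_min + nvv * slope
                    inv_th = 1.0 / th
                    theta[i, j, k] = th
                    wts[i, j, k] = 1.0 - nvv * inv_th
                    wtc[i, j, k] = nt[i, j, k] * inv_th
                    wvs[i, j, k] = 1.0 - nt[i, j, k] * inv_th
                    wvc[i, j, k] = nvv * inv_th
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if not mask[i, j, k]:
                        buf_nt[i, j, k] = 0.0
                        buf_nv[i, j, k] = 0.0
                        continue
                    nt_p = nt[i, j, k]
                    nv_p = nv[i, j, k]
                    div_t = 0.0
                    div_v = 0.0
                    for m in range(6):
                        ii = i + offsets[m, 0]
                        jj = j + offsets[m, 1]
                        kk = k + offsets[m, 2]
                        if ii < 0 or ii >= nx or jj < 0 or jj >= ny or kk < 0 or kk >= nz:
                            continue
                        if not mask[ii, jj, kk]:
                            continue
                        ih2 = inv_h2[m // 2]
                        dtf = 0.5 * (dt_field[i, j, k] + dt_field[ii, jj, kk])
                        dvf = 0.5 * (dv_field[i, j, k] + dv_field[ii, jj, kk])
                        jt = nt[ii, jj, kk] - nt_p
                        jv = nv[ii, jj, kk] - nv_p
                        div_t += dtf * (0.5 * (wts[i, j, k] + wts[ii, jj, kk]) * jt
                                        + 0.5 * (wtc[i, j, k] + wtc[ii, jj, kk]) * jv) * ih2
                        div_v += dvf * (0.5 * (wvs[i, j, k] + wvs[ii, jj, kk]) * jv
                                        + 0.5 * (wvc[i, j, k] + wvc[ii, jj, kk]) * jt) * ih2
                    th = theta[i, j, k]
                    dp = d[i, j, k]
                    nt_new = nt_p + dt * (div_t + kt * nt_p * (1.0 - nt_p / th))
                    nv_new = nv_p + dt * (div_v + kv * nv_p * (1.0 - nv_p / th) * dp
                                          - kdv * nv_p * (1.0 - dp))
                    if nt_new < 0.0:
                        nt_new = 0.0
                    elif nt_new > th:
                        nt_new = th
                    if nv_new < 0.0:
                        nv_new = 0.0
                    elif nv_new > th:
                        nv_new = th
                    buf_nt[i, j, k] = nt_new
                    buf_nv[i, j, k] = nv_new
        nt, buf_nt = buf_nt, nt
        nv, buf_nv = buf_nv, nv
    if n_steps % 2 == 1:
        # result lives in the scratch buffers; copy back into the caller's arrays
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    buf_nt[i, j, k] = nt[i, j, k]
                    buf_nv[i, j, k] = nv[i, j, k]


def _euler_step_numpy(nt, nv, theta, d, dt_field, dv_field, mask, kt, kv, kdv,
                      dt, spacing):
    """Reference numpy implementation of the same update as the compiled kernel."""
    wt_self = np.where(mask, 1.0 - nv / theta, 0.0)
    wt_cross = np.where(mask, nt / theta, 0.0)
    wv_self = np.where(mask, 1.0 - nt / theta, 0.0)
    wv_cross = np.where(mask, nv / theta, 0.0)
    div_t = np.zeros_like(nt)
    div_v = np.zeros_like(nv)
    for axis in range(3):
        ih2 = 1.0 / spacing[axis] ** 2
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        open_face = mask[lo] & mask[hi]
        dtf = 0.5 * (dt_field[lo] + dt_field[hi]) * open_face
        dvf = 0.5 * (dv_field[lo] + dv_field[hi]) * open_face
        jump_t = nt[hi] - nt[lo]
        jump_v = nv[hi] - nv[lo]
        flux_t = dtf * (0.5 * (wt_self[lo] + wt_self[hi]) * jump_t
                        + 0.5 * (wt_cross[lo] + wt_cross[hi]) * jump_v) * ih2
        flux_v = dvf * (0.5 * (wv_self[lo] + wv_self[hi]) * jump_v
                        + 0.5 * (wv_cross[lo] + wv_cross[hi]) * jump_t) * ih2
        div_t[lo] += flux_t
        div_t[hi] -= flux_t
        div_v[lo] += flux_v
        div_v[hi] -= flux_v
    react_t = kt * nt * (1.0 - nt / theta)
    react_v = kv * nv * (1.0 - nv / theta) * d - kdv * nv * (1.0 - d)
    nt_new = nt + dt * (div_t + react_t)
    nv_new = nv + dt * (div_v + react_v)
    nt_new = np.clip(nt_new, 0.0, theta)
    nv_new = np.clip(nv_new, 0.0, theta)
    nt_new[~mask] = 0.0
    nv_new[~mask] = 0.0
    return nt_new, nv_new


def step(
    state: SimulationState,
    params: ModelParameters,
    dt: float,
    check_stability: bool = True,
    use_kernel: bool = True,
) -> SimulationState:
    """One explicit forward-Euler update of the coupled system.

    The carrying capacity, distance map and diffusion fields of ``state``
    are taken as current; the caller is responsible for refreshing them.
    Raises :class:`StabilityError` naming the offending coefficient when the
    step exceeds the stability bound.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if np.any(state.n_t < 0) or np.any(state.n_v < 0):
        raise ValueError("negative input fields")
    if check_stability:
        dt_max = float(state.d_t.max(initial=0.0))
        dv_max = float(state.d_v.max(initial=0.0))
        bound = max_stable_dt(dt_max, dv_max, state.grid.spacing)
        if dt > bound:
            raise StabilityError(
                f"dt={dt} exceeds the stability bound {bound:.3g} day for "
                f"max(D_t)={dt_max:.3g}, max(D_v)={dv_max:.3g} mm^2/day on "
                f"spacing {state.grid.spacing}"
            )
    out_nt = np.empty_like(state.n_t)
    out_nv = np.empty_like(state.n_v)
    if use_kernel:
        inv_h2 = np.array([1.0 / h**2 for h in state.grid.spacing])
        _euler_step_kernel(
            state.n_t, state.n_v, state.theta, state.d, state.d_t, state.d_v,
            state.mask, params.k_t, params.k_v, params.k_dv, dt, inv_h2,
            _OFFSETS, out_nt, out_nv,
        )
    else:
        out_nt, out_nv = _euler_step_numpy(
            state.n_t, state.n_v, state.theta, state.d, state.d_t, state.d_v,
            state.mask, params.k_t, params.k_v, params.k_dv, dt,
            state.grid.spacing,
        )
    theta = carrying_capacity(out_nv, params.theta_min, params.theta_max, params.nv_thresh)
    return SimulationState(
        t=state.t + dt, grid=state.grid, n_t=out_nt, n_v=out_nv, theta=theta,
        d=state.d, d_t=state.d_t, d_v=state.d_v, mask=state.mask,
    )


_AUTO_COARSEN_VOXELS = 6000


def _mechanics_factor(grid: Grid, requested: int) -> int:
    if requested >= 1:
        return requested
    factor = 1
    n = int(np.prod(grid.shape))
    while n // factor**3 > _AUTO_COARSEN_VOXELS and all(
        s % (2 * factor) == 0 for s in grid.shape
    ):
        factor *= 2
    return factor


_coarse_domain_cache: dict = {}


def _coarsened_domain(domain: TissueDomain, factor: int) -> TissueDomain:
    key = (tuple(domain.grid.shape), tuple(domain.grid.spacing),
           domain.shear_modulus.tobytes(), domain.poisson_ratio, factor)
    cached = _coarse_domain_cache.get(key)
    if cached is not None:
        return cached
    grid = domain.grid.coarsen(factor)
    shear = block_mean(domain.shear_modulus, factor)
    mask = block_mean(domain.brain_mask.astype(float), factor) > 0.25
    label = np.where(mask, TissueDomain.LABEL_GRAY, TissueDomain.LABEL_OUTSIDE)
    coarse = TissueDomain(grid, mask, label, shear, domain.poisson_ratio)
    if len(_coarse_domain_cache) > 16:
        _coarse_domain_cache.clear()
    _coarse_domain_cache[key] = coarse
    return coarse


def _refresh_mechanics(n_t: np.ndarray, grid: Grid, domain: TissueDomain,
                       params: ModelParameters,
                       coarsen: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Diffusion fields from a fresh mechanical equilibrium solve.

    For large grids the equilibrium is solved on a block-homogenized coarse
    domain (see :class:`SolverConfig`) and the von Mises field interpolated
    back before the exponential modulation is applied.
    """
    if params.lambda_f == 0.0 or params.gamma_stress == 0.0:
        shape = tuple(grid.shape)
        return (np.full(shape, params.D_t0), np.full(shape, params.D_v0))
    factor = _mechanics_factor(grid, coarsen)
    if factor == 1:
        stress = mechanics.solve_equilibrium(
            ScalarField(grid, n_t, "tumor_fraction"), domain, params.lambda_f
        )
        vm = stress.von_mises.values
    else:
        coarse = _coarsened_domain(domain, factor)
        n_t_c = block_mean(n_t, factor)
        stress = mechanics.solve_equilibrium(
            ScalarField(coarse.grid, n_t_c, "tumor_fraction"), coarse, params.lambda_f
        )
        vm = resample_to_grid(stress.von_mises.values, coarse.grid, grid, order=1)
    d_t = mechanics.stress_modulated_diffusion(params.D_t0, vm, params.gamma_stress)
    d_v = mechanics.stress_modulated_diffusion(params.D_v0, vm, params.gamma_stress)
    return d_t, d_v


def simulate(
    initial: Tuple[ScalarField, ScalarField],
    params: ModelParameters,
    domain: TissueDomain,
    days: int = 10,
    config: SolverConfig | None = None,
) -> TimeCourse:
    """Run the coupled model forward, recording snapshots at integer days.

    Day 1 is the initial condition; the simulation spans ``days - 1``
    simulated days. Deterministic: the forward model contains no randomness.
    """
    if config is None:
        config = SolverConfig()
    if days < 1:
        raise ValueError("days must be >= 1")
    n_t0, n_v0 = initial
    grid = domain.grid
    if n_t0.values.shape != tuple(grid.shape):
        raise ValueError("initial condition grid does not match the domain grid")
    mask = domain.brain_mask
    n_t = np.where(mask, np.clip(n_t0.values, 0.0, None), 0.0)
    n_v = np.where(mask, np.clip(n_v0.values, 0.0, None), 0.0)
    theta = carrying_capacity(n_v, params.theta_min, params.theta_max, params.nv_thresh)
    n_t = np.minimum(n_t, theta)
    n_v = np.minimum(n_v, theta)

    steps_per_day = max(1, int(round(1.0 / config.dt)))
    dt = 1.0 / steps_per_day
    if config.stability_check:
        bound = max_stable_dt(params.D_t0, params.D_v0, grid.spacing)
        if dt > bound:
            raise StabilityError(
                f"dt={dt} exceeds stability bound {bound:.3g} day for "
                f"D_t0={params.D_t0}, D_v0={params.D_v0} on spacing {grid.spacing}"
            )
    mech_every = max(1, int(round(config.mechanics_interval * steps_per_day)))
    if config.d_update_interval is None:
        d_every = 1
    else:
        d_every = max(1, int(round(config.d_update_interval * steps_per_day)))
    thresh = config.tumor_mask_factor * params.theta_max

    d_t, d_v = _refresh_mechanics(n_t, grid, domain, params,
                                  coarsen=config.mechanics_coarsen)
    d_map = distance_to_periphery(n_t, thresh, grid.spacing)

    snapshots: Dict[int, Tuple[np.ndarray, np.ndarray]] = {1: (n_t.copy(), n_v.copy())}
    inv_h2 = np.array([1.0 / h**2 for h in grid.spacing])
    scratch = [np.zeros(grid.shape) for _ in range(5)]
    buf_nt = np.empty(grid.shape)
    buf_nv = np.empty(grid.shape)
    n_t = n_t.copy()
    n_v = n_v.copy()
    step_count = 0
    for day in range(2, days + 1):
        done = 0
        while done < steps_per_day:
            if step_count > 0 and step_count % mech_every == 0:
                d_t, d_v = _refresh_mechanics(n_t, grid, domain, params,
                                              coarsen=config.mechanics_coarsen)
            if step_count % d_every == 0:
                d_map = distance_to_periphery(n_t, thresh, grid.spacing)
            n_chunk = min(
                steps_per_day - done,
                d_every - step_count % d_every,
                mech_every - step_count % mech_every,
            )
            _euler_multistep_kernel(
                n_t, n_v, d_map, d_t, d_v, mask,
                params.k_t, params.k_v, params.k_dv,
                params.theta_min, params.theta_max, params.nv_thresh,
                dt, inv_h2, _OFFSETS, n_chunk,
                scratch[0], scratch[1], scratch[2], scratch[3], scratch[4],
                buf_nt, buf_nv,
            )
            done += n_chunk
            step_count += n_chunk
        snapshots[day] = (n_t.copy(), n_v.copy())
    return TimeCourse(
        grid,
        snapshots,
        parameters=params,
        metadata={
            "dt": dt,
            "mechanics_interval": config.mechanics_interval,
            "d_update_interval": config.d_update_interval,
            "tumor_mask_factor": config.tumor_mask_factor,
        },
    )
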
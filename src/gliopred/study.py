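"""Scaled-down study configuration and SR-specific ground truths.

The reference experiment crosses a 128 x 128 x 16 rat-brain grid, 54
SNR/SR/TR conditions, 13 virtual tumors and up to 50 noise replicates.
This module fixes the desk-scale configuration used throughout the
package's analyses: the finest spatial resolution (0.008 mm^3 voxels of
0.125 x 0.125 x 0.5 mm) is discretized on a 32 x 32 x 16 grid spanning a
4 x 4 x 8 mm box around a synthetic brain, and the two coarser study
resolutions follow by factor-2 per-axis degradation (16 x 16 x 8 and
8 x 8 x 4). Initial
conditions are synthesized once on the finest grid and resampled to each
SR, after which each SR's noiseless ground truth is simulated on its own
grid — coarser data are coarser simulations, not smoothed fine ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

from .grids import Grid, ScalarField
from .cohort import ModelParameters
from .domain import (
    DomainConfig,
    LesionConfig,
    TissueDomain,
    build_tissue_domain,
    synthesize_initial_conditions,
)
from .degrade import VOXEL_VOLUMES, resample
from .growth import SolverConfig, TimeCourse, simulate

__all__ = ["StudyConfig", "study_grids", "ground_truth_course", "clear_ground_truth_cache"]


@dataclass(frozen=True)
class StudyConfig:
    """Problem sizes and numerical cadences of the scaled-down study."""

    fine_shape: Tuple[int, int, int] = (32, 32, 16)
    fine_spacing: Tuple[float, float, float] = (0.125, 0.125, 0.5)  # mm
    # lesion diameter covers >= 4 coarse in-plane voxels (so the tumor front
    # stays resolved at every study SR, as in the reference geometry) and the
    # brain leaves ~0.85 mm of free margin for front motion over the 4
    # calibration days (front speed ~ 2 sqrt(D k) ~ 0.22 mm/day)
    domain: DomainConfig = field(default_factory=lambda: DomainConfig(
        brain_semiaxes=(1.85, 1.85, 2.6)))
    lesion: LesionConfig = field(default_factory=lambda: LesionConfig(radius=1.0))
    solver: SolverConfig = field(default_factory=lambda: SolverConfig(
        dt=0.02, mechanics_interval=2.0, d_update_interval=0.2))
    horizon: int = 10
    domain_seed: int = 1234
    metric_threshold_factor: float = 0.05

    @property
    def metric_threshold(self) -> float:
        """Absolute detection/binarization threshold on volume fractions."""
        return self.metric_threshold_factor * ModelParameters().theta_max

    # imported lazily to avoid a circular import; kept here so one object
    # carries the whole study configuration
    @property
    def calibration(self):
        from .calibrate import CalibrationConfig

        # diffusivity cap 0.08 mm^2/day keeps dt = 0.02 inside the explicit
        # stability bound on the finest study grid while leaving ample room
        # above the largest cohort diffusivity (0.046 mm^2/day)
        return CalibrationConfig(
            upper=(0.08, 0.08, 5.0, 5.0),
            max_iterations=20,
            ftol=1e-5,
            jacobian_refresh=2,
            solver=self.solver,
        )


def study_grids(study: StudyConfig | None = None) -> Dict[float, Grid]:
    """Map study voxel volume (mm^3) -> grid, finest first."""
    if study is None:
        study = StudyConfig()
    fine = Grid(study.fine_shape, study.fine_spacing)
    return {
        VOXEL_VOLUMES[0]: fine,
        VOXEL_VOLUMES[1]: fine.coarsen(2),
        VOXEL_VOLUMES[2]: fine.coarsen(4),
    }


_gt_cache: dict = {}


def clear_ground_truth_cache() -> None:
    _gt_cache.clear()


def ground_truth_course(
    params: ModelParameters,
    voxel_volume: float,
    study: StudyConfig | None = None,
    use_cache: bool = True,
) -> Tuple[TimeCourse, TissueDomain]:
    """Noiseless ground-truth time course at one study spatial resolution.

    The brain domain is evaluated analytically on the SR's grid (the same
    geometry at every SR); the initial conditions are synthesized on the
    finest grid and resampled down; the model is then run on the SR's grid
    for the full horizon. Memoized per (parameters, SR, study) because the
    orchestrator revisits each ground truth across conditions and
    replicates.
    """
    if study is None:
        study = StudyConfig()
    key = (params, float(voxel_volume), study)
    if use_cache and key in _gt_cache:
        return _gt_cache[key]
    grids = study_grids(study)
    if voxel_volume not in grids:
        raise ValueError(f"voxel volume {voxel_volume} is not a study resolution")
    fine_grid = grids[VOXEL_VOLUMES[0]]
    fine_domain = build_tissue_domain(fine_grid, study.domain, seed=study.domain_seed)
    n_t0, n_v0 = synthesize_initial_conditions(fine_domain, study.lesion,
                                               seed=study.domain_seed)
    if voxel_volume == VOXEL_VOLUMES[0]:
        domain, n_t, n_v = fine_domain, n_t0, n_v0
    else:
        domain = build_tissue_domain(grids[voxel_volume], study.domain,
                                     seed=study.domain_seed)
        theta_max = params.theta_max
        n_t = resample(n_t0, voxel_volume, clip_max=theta_max)
        n_v = resample(n_v0, voxel_volume, clip_max=theta_max)
        n_t = ScalarField(domain.grid, n_t.values * domain.brain_mask, "tumor_fraction")
        n_v = ScalarField(domain.grid, n_v.values * domain.brain_mask,
                          "vasculature_fraction")
    course = simulate((n_t, n_v), params, domain, days=study.horizon,
                      config=study.solver)
    if use_cache:
        if len(_gt_cache) > 64:
            _gt_cache.clear()
        _gt_cache[key] = (course, domain)
    return course, domain
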
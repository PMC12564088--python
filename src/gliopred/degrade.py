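"""In silico imaging degradation: SNR, spatial resolution, temporal resolution.

Ground-truth fields are degraded to emulate imaging at a chosen quality:

* SNR — each voxel is multiplied by an independent Normal(1, 1/SNR) draw
  (multiplicative noise; zeros stay zero), then clipped to [0, theta_max]
  to keep volume fractions physical.
* SR — fields are resampled by trilinear interpolation between voxel-center
  grids; the per-axis voxel size scales by the same factor, moving between
  the three study voxel volumes 0.008, 0.063 and 0.50 mm^3 (factors 1/2,
  1 and 2 relative to the 0.063 mm^3 base).
* TR — only a subset of imaging days (1&5; 1,3,5; or 1-5) is kept for
  calibration.

The full experiment grid crosses 6 SNR levels, 3 voxel volumes and 3
timepoint schedules: 54 conditions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

from .grids import Grid, ScalarField, resample_to_grid
from .growth import TimeCourse

__all__ = [
    "SNR_LEVELS",
    "VOXEL_VOLUMES",
    "TR_SCHEDULES",
    "ExperimentCondition",
    "condition_grid",
    "condition_manifest",
    "add_noise",
    "resample",
    "select_timepoints",
    "degrade",
]

SNR_LEVELS = (5, 10, 20, 40, 80, 160)
VOXEL_VOLUMES = (0.008, 0.063, 0.50)  # mm^3
TR_SCHEDULES = ((1, 5), (1, 3, 5), (1, 2, 3, 4, 5))


@dataclass(frozen=True)
class ExperimentCondition:
    """One SNR x SR x TR cell of the experiment grid plus its noise seed."""

    snr: float
    voxel_volume: float
    tr_days: Tuple[int, ...]
    replicate_seed: int = 0

    def __post_init__(self) -> None:
        if self.snr not in SNR_LEVELS:
            raise ValueError(f"snr must be one of {SNR_LEVELS}, got {self.snr}")
        if self.voxel_volume not in VOXEL_VOLUMES:
            raise ValueError(f"voxel volume must be one of {VOXEL_VOLUMES}")
        if tuple(self.tr_days) not in TR_SCHEDULES:
            raise ValueError(f"tr_days must be one of {TR_SCHEDULES}")

    @property
    def condition_id(self) -> str:
        return f"snr{self.snr:g}_sr{self.voxel_volume:g}_tr{len(self.tr_days)}"


def condition_grid(base_seed: int = 0) -> list[ExperimentCondition]:
    """The 54 experiment conditions (6 SNR x 3 SR x 3 TR), distinct ids.

    ``replicate_seed`` is a per-cell counter offset from ``base_seed``; the
    orchestrator derives per-replicate noise streams from it.
    """
    conditions = []
    for i, (snr, vol, tr) in enumerate(
        itertools.product(SNR_LEVELS, VOXEL_VOLUMES, TR_SCHEDULES)
    ):
        conditions.append(ExperimentCondition(snr, vol, tr, replicate_seed=base_seed + i))
    return conditions


def condition_manifest(conditions: Sequence[ExperimentCondition]) -> dict:
    """JSON-ready manifest mapping condition-id -> its settings and seed."""
    return {
        c.condition_id: {"snr": c.snr, "voxel_volume": c.voxel_volume,
                         "tr_days": list(c.tr_days),
                         "replicate_seed": c.replicate_seed}
        for c in conditions
    }


def add_noise(field_: ScalarField, snr: float, seed: int,
              clip_max: float = 0.9716) -> ScalarField:
    """Multiplicative Gaussian noise at the given SNR, clipped to [0, clip_max].

    Each voxel is scaled by an independent Normal(1, 1/snr) draw;
    deterministic per seed; zeros are preserved exactly.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    rng = np.random.default_rng(seed)
    factors = rng.normal(1.0, 1.0 / snr, size=field_.values.shape)
    noisy = np.clip(field_.values * factors, 0.0, clip_max)
    return field_.with_values(noisy)


def resample(field_: ScalarField, target_voxel_volume: float,
             order: int = 1, clip_max: float | None = 0.9716) -> ScalarField:
    """Resample a field to one of the study voxel volumes.

    The linear scale factor is applied equally along every axis (the grids
    are anisotropic; their per-axis spacings all scale by the same factor).
    Trilinear interpolation by default (``order=1``), which reproduces
    constants exactly and cannot overshoot fraction bounds; ``order=3``
    selects cubic interpolation for strict emulation of image-resize
    pipelines. Volume-fraction outputs are clipped to [0, clip_max].
    """
    if target_voxel_volume not in VOXEL_VOLUMES:
        raise ValueError(f"target voxel volume must be one of {VOXEL_VOLUMES}")
    source = field_.grid
    # the study voxel volumes are rounded labels (0.008 ~ 0.125^2*0.5 mm^3),
    # so match the linear factor to the nearest integer with a 5% tolerance
    factor = (target_voxel_volume / source.voxel_volume) ** (1.0 / 3.0)
    if 0.95 < factor < 1.05:
        return field_.copy()
    if factor > 1:
        step = int(round(factor))
        if step < 2 or abs(factor / step - 1.0) > 0.05:
            raise ValueError(
                f"voxel-volume ratio {target_voxel_volume / source.voxel_volume:g} "
                "is not an integer-cubed down-sampling factor"
            )
        target = source.coarsen(step)
    else:
        step = int(round(1.0 / factor))
        if step < 2 or abs(1.0 / (factor * step) - 1.0) > 0.05:
            raise ValueError(
                f"voxel-volume ratio {target_voxel_volume / source.voxel_volume:g} "
                "is not an integer-cubed up-sampling factor"
            )
        target = source.refine(step)
    out = resample_to_grid(field_.values, source, target, order=order)
    if clip_max is not None:
        out = np.clip(out, 0.0, clip_max)
    return ScalarField(target, out, field_.role)


def select_timepoints(tc: TimeCourse, tr_days: Sequence[int]) -> TimeCourse:
    """Keep only the requested imaging days of a time course.

    Equivalent to calibrating with unit weights on the selected days and
    zero weights elsewhere. Requesting a missing day is an error.
    """
    missing = [d for d in tr_days if d not in tc.snapshots]
    if missing:
        raise ValueError(f"days {missing} not present in the time course (has {tc.days})")
    subset = {int(d): tc.snapshots[d] for d in tr_days}
    return TimeCourse(tc.grid, subset, parameters=tc.parameters,
                      metadata={**tc.metadata, "tr_days": tuple(int(d) for d in tr_days)})


def degrade(tc: TimeCourse, cond: ExperimentCondition, replicate: int = 0,
            clip_max: float = 0.9716, noiseless: bool = False) -> TimeCourse:
    """Produce one replicate of in silico experimental data from ground truth.

    ``tc`` must already be the SR-specific ground truth at the condition's
    spatial resolution. Noise draws are independent per day and per species,
    derived deterministically from ``(cond.replicate_seed, replicate)``.
    ``noiseless=True`` is the infinite-SNR surrogate: only timepoint
    selection is applied.
    """
    if not np.isclose(tc.grid.voxel_volume, cond.voxel_volume, rtol=0.05):
        raise ValueError(
            f"time course voxel volume {tc.grid.voxel_volume:g} mm^3 does not match "
            f"condition SR {cond.voxel_volume:g} mm^3"
        )
    subset = select_timepoints(tc, cond.tr_days)
    if noiseless:
        return subset
    root = np.random.SeedSequence(entropy=int(cond.replicate_seed),
                                  spawn_key=(int(replicate),))
    degraded = {}
    for day in subset.days:
        day_seq = root.spawn(1)[0]
        seeds = day_seq.generate_state(2)
        n_t = add_noise(subset.tumor(day), cond.snr, int(seeds[0]) % (2**31),
                        clip_max=clip_max)
        n_v = add_noise(subset.vasculature(day), cond.snr, int(seeds[1]) % (2**31),
                        clip_max=clip_max)
        degraded[day] = (n_t.values, n_v.values)
    return TimeCourse(tc.grid, degraded, parameters=tc.parameters,
                      metadata={**subset.metadata, "snr": cond.snr,
                                "replicate": replicate})
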
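"""Synthetic brain domain and tumor/vasculature initial conditions.

The computational domain is a parametric stand-in for a segmented rat brain:
an ellipsoidal brain mask containing a white-matter shell embedded in gray
matter. White matter is stiffer (shear modulus 800 Pa) than gray matter
(466 Pa), which is what the mechanical coupling needs from the anatomy.
The generator is synthetic by construction — it does not reproduce any real
atlas geometry, only the two-tissue mechanical heterogeneity.

Initial conditions place a smooth, radially symmetric tumor lesion at the
brain center with a co-localized vascular bed, emulating cellularity and
blood-volume maps derived from diffusion-weighted and dynamic
contrast-enhanced MRI of a C6 glioma.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .grids import Grid, ScalarField

__all__ = [
    "DomainConfig",
    "TissueDomain",
    "build_tissue_domain",
    "LesionConfig",
    "synthesize_initial_conditions",
    "SHEAR_MODULUS_WHITE",
    "SHEAR_MODULUS_GRAY",
]

SHEAR_MODULUS_WHITE = 800.0  # Pa
SHEAR_MODULUS_GRAY = 466.0  # Pa


class DomainConstructionError(ValueError):
    """Raised when the requested geometry cannot fit on the grid."""


@dataclass(frozen=True)
class DomainConfig:
    """Geometry of the synthetic brain.

    ``brain_semiaxes`` are the ellipsoid semi-axes in mm (None: 90% of the
    half-extent per axis, leaving a margin at the box boundary). White matter
    occupies an ellipsoidal shell between ``white_inner`` and ``white_outer``
    fractions of the brain semi-axes; ``white_wobble`` adds a seeded smooth
    angular modulation of the shell radii so domains differ across seeds.
    """

    brain_semiaxes: Tuple[float, float, float] | None = None
    white_inner: float = 0.45
    white_outer: float = 0.75
    white_wobble: float = 0.08
    poisson_ratio: float = 0.45

    def __post_init__(self) -> None:
        if not 0.0 <= self.white_inner <= self.white_outer <= 1.0:
            raise ValueError("need 0 <= white_inner <= white_outer <= 1")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")


@dataclass
class TissueDomain:
    """Brain mask, tissue labels and mechanical properties on a grid.

    ``tissue_label`` is 0 outside the brain, 1 for gray matter, 2 for white
    matter. The shear-modulus map is 800 Pa on white and 466 Pa on gray
    voxels; outside the mask it holds the gray value, which is inert because
    all fields (and hence all body forces) vanish there.
    """

    grid: Grid
    brain_mask: np.ndarray
    tissue_label: np.ndarray
    shear_modulus: np.ndarray
    poisson_ratio: float

    LABEL_OUTSIDE = 0
    LABEL_GRAY = 1
    LABEL_WHITE = 2

    def __post_init__(self) -> None:
        shape = tuple(self.grid.shape)
        for name in ("brain_mask", "tissue_label", "shear_modulus"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != grid shape {shape}")

    @property
    def n_voxels_inside(self) -> int:
        return int(self.brain_mask.sum())


def _radial_wobble(xn: np.ndarray, yn: np.ndarray, zn: np.ndarray, amp: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Smooth seeded modulation field of order 1 +/- amp on the unit sphere."""
    if amp == 0.0:
        return np.ones_like(xn)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    weights = rng.uniform(0.5, 1.0, size=3)
    weights /= weights.sum()
    mod = (
        weights[0] * np.sin(2.0 * np.pi * xn + phases[0])
        + weights[1] * np.sin(2.0 * np.pi * yn + phases[1])
        + weights[2] * np.sin(2.0 * np.pi * zn + phases[2])
    )
    return 1.0 + amp * mod


def build_tissue_domain(grid: Grid, config: DomainConfig | None = None,
                        seed: int = 0) -> TissueDomain:
    """Construct the synthetic two-tissue brain domain.

    Deterministic for a fixed seed. Raises :class:`DomainConstructionError`
    if the grid is too small to hold both tissue classes with at least one
    voxel of margin at the box boundary.
    """
    if config is None:
        config = DomainConfig()
    if any(n < 4 for n in grid.shape):
        raise DomainConstructionError(
            f"grid shape {grid.shape} too small for a two-tissue brain (need >= 4 per axis)"
        )
    rng = np.random.default_rng(seed)
    cx, cy, cz = grid.center
    half_extent = [0.5 * e for e in grid.extent]
    if config.brain_semiaxes is None:
        semi = tuple(0.9 * h for h in half_extent)
    else:
        semi = config.brain_semiaxes
        if any(s >= h for s, h in zip(semi, half_extent)):
            raise DomainConstructionError(
                f"brain semi-axes {semi} exceed the grid half-extent {tuple(half_extent)}"
            )
    X, Y, Z = grid.meshgrid()
    xn = (X - cx) / semi[0]
    yn = (Y - cy) / semi[1]
    zn = (Z - cz) / semi[2]
    r = np.sqrt(xn**2 + yn**2 + zn**2)
    brain_mask = r <= 1.0
    # guarantee the 1-voxel boundary margin regardless of semi-axis rounding
    brain_mask[0, :, :] = brain_mask[-1, :, :] = False
    brain_mask[:, 0, :] = brain_mask[:, -1, :] = False
    brain_mask[:, :, 0] = brain_mask[:, :, -1] = False
    if not brain_mask.any():
        raise DomainConstructionError("brain mask is empty on this grid")

    label = np.where(brain_mask, TissueDomain.LABEL_GRAY, TissueDomain.LABEL_OUTSIDE)
    if config.white_outer > config.white_inner:
        wobble = _radial_wobble(xn, yn, zn, config.white_wobble, rng)
        inner = config.white_inner * wobble
        outer = config.white_outer * wobble
        white = brain_mask & (r >= inner) & (r <= outer)
        label[white] = TissueDomain.LABEL_WHITE
        if not white.any() and config.white_outer > 0:
            raise DomainConstructionError("white-matter shell contains no voxels on this grid")
    shear = np.full(grid.shape, SHEAR_MODULUS_GRAY)
    shear[label == TissueDomain.LABEL_WHITE] = SHEAR_MODULUS_WHITE
    return TissueDomain(grid, brain_mask, label, shear, config.poisson_ratio)


@dataclass(frozen=True)
class LesionConfig:
    """Seed lesion for the tumor and its vascular bed.

    The tumor profile is a radially symmetric plateau with a smooth sigmoid
    edge: N_t(r) = peak / (1 + exp((r - radius)/edge_width)). The vascular
    bed is a co-localized Gaussian, N_v(r) = peak_v * exp(-r^2 / (2 sigma^2))
    with sigma = ``vasc_sigma_factor * radius``, so vasculature is present
    within and around the lesion and negligible far from it.
    """

    radius: float = 0.8  # mm
    edge_width_factor: float = 1.0 / 6.0  # edge width as a fraction of radius
    peak_tumor_fraction: float = 0.9716  # = theta_max by default
    peak_vasc_fraction: float = 0.05
    vasc_sigma_factor: float = 1.0


def synthesize_initial_conditions(
    domain: TissueDomain,
    tumor_config: LesionConfig | None = None,
    seed: int = 0,
) -> tuple[ScalarField, ScalarField]:
    """Smooth tumor and vasculature seed fields centered in the brain mask.

    Both fields are zero outside the brain mask and bounded by the peak
    fractions. A zero-radius lesion yields identically zero fields. The
    construction is deterministic (the seed is recorded for protocol
    symmetry with the domain generator but draws nothing at present).
    Isotropic configs are invariant under grid-axis permutation.
    """
    if tumor_config is None:
        tumor_config = LesionConfig()
    cfg = tumor_config
    grid = domain.grid
    half_extent = min(0.5 * e for e in grid.extent)
    if cfg.radius > half_extent:
        raise ValueError(
            f"lesion radius {cfg.radius} mm exceeds the brain half-extent {half_extent} mm"
        )
    if cfg.radius == 0.0:
        zero = np.zeros(grid.shape)
        return (
            ScalarField(grid, zero, "tumor_fraction"),
            ScalarField(grid, zero.copy(), "vasculature_fraction"),
        )
    X, Y, Z = grid.meshgrid()
    cx, cy, cz = grid.center
    r = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
    w = cfg.edge_width_factor * cfg.radius
    n_t = cfg.peak_tumor_fraction / (1.0 + np.exp((r - cfg.radius) / w))
    sigma = cfg.vasc_sigma_factor * cfg.radius
    n_v = cfg.peak_vasc_fraction * np.exp(-0.5 * (r / sigma) ** 2)
    inside = domain.brain_mask
    n_t = np.where(inside, n_t, 0.0)
    n_v = np.where(inside, n_v, 0.0)
    return (
        ScalarField(grid, n_t, "tumor_fraction"),
        ScalarField(grid, n_v, "vasculature_fraction"),
    )
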
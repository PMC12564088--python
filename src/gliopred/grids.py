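"""Regular voxel grids and scalar fields.

All fields in this package live on axis-aligned regular grids with axis order
(x, y, z), 0-based voxel indices and voxel-center world coordinates in mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = ["Grid", "ScalarField", "FIELD_ROLES", "resample_to_grid", "block_mean"]

FIELD_ROLES = frozenset(
    {
        "tumor_fraction",
        "vasculature_fraction",
        "adc",
        "concentration",
        "stress",
        "distance",
        "capacity",
        "generic",
    }
)


@dataclass(frozen=True)
class Grid:
    """Geometry of a regular voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z); each entry >= 1.
    spacing
        Voxel edge length in mm along each axis; each entry > 0.
    origin
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("Grid is three-dimensional: shape/spacing/origin need 3 entries")
        if any(n < 1 for n in shape):
            raise ValueError(f"all grid shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all grid spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> Tuple[float, float, float]:
        """Physical edge length of the grid (mm) along each axis."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def meshgrid(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinate arrays (X, Y, Z), each of ``self.shape``."""
        ax = [self.axis_coordinates(i) for i in range(3)]
        return np.meshgrid(*ax, indexing="ij")

    @property
    def center(self) -> Tuple[float, float, float]:
        """World coordinate of the grid's geometric center."""
        return tuple(
            o + 0.5 * s * (n - 1) for o, s, n in zip(self.origin, self.spacing, self.shape)
        )

    def coarsen(self, factor: int) -> "Grid":
        """Grid covering the same physical extent with ``factor``-times larger voxels.

        Voxel centers of the coarse grid sit at the centroid of each
        ``factor``-cube of fine voxels, so the physical field of view is
        preserved exactly when the shape divides evenly.
        """
        if factor < 1:
            raise ValueError("coarsening factor must be >= 1")
        if any(n % factor for n in self.shape):
            raise ValueError(f"shape {self.shape} not divisible by factor {factor}")
        shape = tuple(n // factor for n in self.shape)
        spacing = tuple(s * factor for s in self.spacing)
        origin = tuple(o + 0.5 * s * (factor - 1) for o, s in zip(self.origin, self.spacing))
        return Grid(shape, spacing, origin)

    def refine(self, factor: int) -> "Grid":
        """Inverse of :meth:`coarsen`: same extent, ``factor``-times smaller voxels."""
        if factor < 1:
            raise ValueError("refinement factor must be >= 1")
        shape = tuple(n * factor for n in self.shape)
        spacing = tuple(s / factor for s in self.spacing)
        origin = tuple(o - 0.5 * sp * (factor - 1) for o, sp in zip(self.origin, spacing))
        return Grid(shape, spacing, origin)


@dataclass
class ScalarField:
    """A scalar value per voxel of a :class:`Grid`, tagged with its physical role."""

    grid: Grid
    values: np.ndarray
    role: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )
        if self.role not in FIELD_ROLES:
            raise ValueError(f"unknown field role {self.role!r}")

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy(), self.role)

    def with_values(self, values: np.ndarray, role: str | None = None) -> "ScalarField":
        return ScalarField(self.grid, values, self.role if role is None else role)

    def integral(self) -> float:
        """Integral of the field over the grid (value * voxel volume summed)."""
        return float(self.values.sum() * self.grid.voxel_volume)

    def same_grid(self, other: "ScalarField") -> bool:
        return self.grid == other.grid


def resample_to_grid(values: np.ndarray, source: Grid, target: Grid,
                     order: int = 1) -> np.ndarray:
    """Interpolate voxel-center values from one grid onto another.

    Target voxel centers are mapped to fractional source indices through
    world (mm) coordinates; interpolation is spline of the given order
    (1 = trilinear) with nearest-edge extension.
    """
    from scipy import ndimage  # local import keeps module import light

    coords = []
    for axis in range(3):
        t = target.axis_coordinates(axis)
        coords.append((t - source.origin[axis]) / source.spacing[axis])
    cx, cy, cz = np.meshgrid(*coords, indexing="ij")
    return ndimage.map_coordinates(values, np.stack([cx, cy, cz]), order=order,
                                   mode="nearest")


def block_mean(values: np.ndarray, factor: int) -> np.ndarray:
    """Mean over non-overlapping ``factor``-cubes (shape must divide evenly)."""
    nx, ny, nz = values.shape
    if any(n % factor for n in values.shape):
        raise ValueError(f"shape {values.shape} not divisible by {factor}")
    return values.reshape(nx // factor, factor, ny // factor, factor,
                          nz // factor, factor).mean(axis=(1, 3, 5))
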
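"""MRI-to-volume-fraction converters.

Tumor cellularity is estimated from the apparent diffusion coefficient of
diffusion-weighted MRI: voxels with freely diffusing water (ADC of free
water at 37 C, ~3e-3 mm^2/s) carry no tumor, and the voxel with the minimum
ADC in the field of view carries the maximum fraction theta_max:

    N_t = theta_max * (ADC_w - ADC) / (ADC_w - ADC_min)

Vascular volume fraction is estimated from dynamic contrast-enhanced MRI as
the ratio of the early contrast-concentration integral in a voxel to the
integral of the arterial input function (the concentration in pure blood)
over the same window, so a pure-blood voxel maps to N_v = 1.
"""

from __future__ import annotations

import numpy as np

from .grids import Grid, ScalarField

__all__ = [
    "ADC_FREE_WATER",
    "adc_to_cellularity",
    "dce_to_vascularity",
    "synthetic_adc_map",
    "synthetic_dce_course",
]

ADC_FREE_WATER = 3.0e-3  # mm^2/s at 37 C


class DegenerateInputError(ValueError):
    """Raised when an input field admits no meaningful conversion."""


def adc_to_cellularity(
    adc: ScalarField,
    theta_max: float = 0.9716,
    adc_w: float = ADC_FREE_WATER,
) -> ScalarField:
    """Map an ADC field (mm^2/s) to a tumor volume-fraction field.

    ADC_min is the minimum ADC within the field of view, computed from the
    field itself. The output is affine-decreasing in ADC and clipped to
    [0, theta_max]. A constant ADC field makes the denominator vanish and
    raises :class:`DegenerateInputError`.
    """
    values = adc.values
    if np.any(values <= 0):
        raise ValueError("ADC values must be positive")
    adc_min = float(values.min())
    denom = adc_w - adc_min
    if denom <= 0:
        raise DegenerateInputError(
            f"minimum ADC {adc_min} is not below the free-water ADC {adc_w}; "
            "cellularity is undefined"
        )
    if np.isclose(float(values.max()), adc_min):
        raise DegenerateInputError("constant ADC field: ADC_min equals ADC everywhere")
    n_t = theta_max * (adc_w - values) / denom
    n_t = np.clip(n_t, 0.0, theta_max)
    return ScalarField(adc.grid, n_t, "tumor_fraction")


def dce_to_vascularity(
    concentration: np.ndarray,
    times: np.ndarray,
    aif: np.ndarray,
    grid: Grid,
    window_s: float = 60.0,
) -> ScalarField:
    """Map a DCE concentration time course to a blood volume-fraction field.

    Parameters
    ----------
    concentration
        Array of shape ``(n_times, *grid.shape)``: contrast concentration per
        voxel at each sample time after injection.
    times
        Sample times in seconds, shared by voxel curves and the AIF.
    aif
        Arterial input function sampled at ``times``; must be strictly
        positive within the integration window.
    window_s
        Integration window after injection (default 60 s).

    N_v is the ratio of time integrals over the window:
    ``N_v = int_0^T C dt / int_0^T AIF dt``, which is 1 for a voxel whose
    curve equals the AIF and linear in C for a fixed AIF.
    """
    times = np.asarray(times, dtype=float)
    aif = np.asarray(aif, dtype=float)
    concentration = np.asarray(concentration, dtype=float)
    if times.ndim != 1 or aif.shape != times.shape:
        raise ValueError("AIF and times must be 1-D arrays on a common time base")
    if concentration.shape != (times.size, *grid.shape):
        raise ValueError(
            f"concentration shape {concentration.shape} does not match "
            f"(n_times, *grid.shape) = {(times.size, *grid.shape)}"
        )
    in_window = times <= window_s
    if in_window.sum() < 2:
        raise ValueError("need at least two samples inside the integration window")
    t = times[in_window]
    if np.any(aif[in_window] <= 0):
        raise ValueError("AIF must be strictly positive over the integration window")
    aif_integral = np.trapezoid(aif[in_window], t)
    if aif_integral <= 0:
        raise ValueError("nonpositive AIF integral")
    conc_integral = np.trapezoid(concentration[in_window], t, axis=0)
    n_v = conc_integral / aif_integral
    return ScalarField(grid, n_v, "vasculature_fraction")


def synthetic_adc_map(n_t: ScalarField, theta_max: float = 0.9716,
                      adc_w: float = ADC_FREE_WATER,
                      adc_min: float = 0.5e-3) -> ScalarField:
    """Emulated ADC map whose cellularity conversion recovers ``n_t``.

    Inverts the cellularity mapping with the stated floor ``adc_min`` reached
    exactly where ``n_t`` attains ``theta_max``; useful for exercising the
    converter round trip without scanner data.
    """
    frac = np.clip(n_t.values / theta_max, 0.0, 1.0)
    adc = adc_w - frac * (adc_w - adc_min)
    return ScalarField(n_t.grid, adc, "adc")


def synthetic_dce_course(
    n_v: ScalarField,
    times: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Emulated DCE data (concentration, times, AIF) consistent with ``n_v``.

    The AIF is a gamma-variate bolus; each voxel curve is the AIF scaled by
    the local blood volume fraction, so the ratio-of-integrals conversion
    recovers ``n_v`` exactly.
    """
    if times is None:
        times = np.linspace(0.0, 60.0, 31)
    times = np.asarray(times, dtype=float)
    t = np.maximum(times, 1e-9)
    aif = (t / 10.0) ** 2 * np.exp(-(t - 10.0) / 12.0)
    aif = aif / aif.max() + 1e-6
    concentration = n_v.values[None, ...] * aif[:, None, None, None]
    return concentration, times, aif
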
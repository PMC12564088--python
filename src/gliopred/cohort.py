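"""Model parameters and the virtual-tumor cohort.

The forward model has four globally calibrated parameters — the stress-free
diffusion coefficients of tumor cells (D_t0) and vasculature (D_v0), and
their logistic proliferation rates (k_t, k_v) — plus fixed constants: the
carrying-capacity bounds (theta_min, theta_max), the vasculature fraction
supporting full capacity (nv_thresh), the vessel regression rate (k_dv), the
stress-diffusion coupling (gamma_stress, per kPa) and the mechanical force
coupling (lambda_f, Pa per unit tumor fraction).

The cohort consists of a "central" tumor carrying the calibrated rat values
and twelve variants obtained by jointly offsetting the proliferation pair
(k_t, k_v) and the diffusion pair (D_t0, D_v0) by +/-25, 50 or 75 percent.
Tumor IDs use a quadrant digit (1: +proliferation/+diffusion,
2: +proliferation/-diffusion, 3: -proliferation/+diffusion,
4: -proliferation/-diffusion) followed by a magnitude digit
(1: 25%, 2: 50%, 3: 75%).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from typing import List, Tuple

__all__ = [
    "ModelParameters",
    "VirtualTumorSpec",
    "central_parameters",
    "build_virtual_cohort",
    "CALIBRATED_NAMES",
]

#: Names of the four globally calibrated parameters, in calibration order.
CALIBRATED_NAMES = ("D_t0", "D_v0", "k_t", "k_v")


@dataclass(frozen=True)
class ModelParameters:
    """Rates and coefficients of the coupled tumor/vasculature model."""

    D_t0: float = 0.0263  # tumor diffusion, mm^2/day, stress-free
    D_v0: float = 0.0100  # vasculature diffusion, mm^2/day, stress-free
    k_t: float = 0.45  # tumor proliferation, 1/day
    k_v: float = 0.25  # vasculature proliferation, 1/day
    k_dv: float = 0.125  # vessel regression rate, 1/day
    theta_min: float = 0.1  # carrying capacity with no vasculature
    theta_max: float = 0.9716  # carrying capacity with full vascular support
    nv_thresh: float = 0.022  # N_v fraction supporting theta_max
    gamma_stress: float = 0.25  # diffusion-stress coupling, 1/kPa
    lambda_f: float = 2000.0  # tumor-gradient force coupling, Pa

    def __post_init__(self) -> None:
        for name in ("D_t0", "D_v0", "k_t", "k_v", "k_dv", "gamma_stress", "lambda_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not self.theta_min < self.theta_max:
            raise ValueError("theta_min must be < theta_max")
        if not 0.0 < self.nv_thresh < 1.0:
            raise ValueError("nv_thresh must lie in (0, 1)")

    def calibrated_vector(self) -> Tuple[float, float, float, float]:
        """The four calibrated parameters as (D_t0, D_v0, k_t, k_v)."""
        return (self.D_t0, self.D_v0, self.k_t, self.k_v)

    def with_calibrated(self, vec) -> "ModelParameters":
        """Copy with the four calibrated parameters replaced by ``vec``."""
        d_t0, d_v0, k_t, k_v = (float(v) for v in vec)
        return replace(self, D_t0=d_t0, D_v0=d_v0, k_t=k_t, k_v=k_v)

    def to_dict(self) -> dict:
        return asdict(self)


def central_parameters() -> ModelParameters:
    """Parameters of the central virtual tumor (the calibrated rat values)."""
    return ModelParameters()


@dataclass(frozen=True)
class VirtualTumorSpec:
    """One member of the virtual-tumor cohort.

    ``proliferation_offset`` and ``diffusion_offset`` are the signed percent
    offsets applied jointly to (k_t, k_v) and (D_t0, D_v0) respectively.
    """

    tumor_id: str
    parameters: ModelParameters
    proliferation_offset: float = 0.0
    diffusion_offset: float = 0.0

    _ALLOWED = (0.0, 25.0, -25.0, 50.0, -50.0, 75.0, -75.0)

    def __post_init__(self) -> None:
        if self.proliferation_offset not in self._ALLOWED:
            raise ValueError(f"proliferation offset must be one of {self._ALLOWED}")
        if self.diffusion_offset not in self._ALLOWED:
            raise ValueError(f"diffusion offset must be one of {self._ALLOWED}")


_QUADRANTS = {1: (+1, +1), 2: (+1, -1), 3: (-1, +1), 4: (-1, -1)}
_MAGNITUDES = {1: 25.0, 2: 50.0, 3: 75.0}


def build_virtual_cohort(central: ModelParameters | None = None) -> List[VirtualTumorSpec]:
    """The 13-tumor cohort: the central tumor plus 4 quadrants x 3 magnitudes.

    Quadrant 1 offsets both proliferation rates and both diffusion
    coefficients up, quadrant 4 offsets all four down; quadrants 2 and 3 mix
    signs (see module docstring). k_dv and all fixed constants are shared.
    A pure function: calling it twice yields identical specs.
    """
    if central is None:
        central = central_parameters()
    cohort = [VirtualTumorSpec("central", central)]
    for quad, (sp, sd) in _QUADRANTS.items():
        for mag, pct in _MAGNITUDES.items():
            fp = 1.0 + sp * pct / 100.0
            fd = 1.0 + sd * pct / 100.0
            params = replace(
                central,
                k_t=central.k_t * fp,
                k_v=central.k_v * fp,
                D_t0=central.D_t0 * fd,
                D_v0=central.D_v0 * fd,
            )
            cohort.append(
                VirtualTumorSpec(
                    tumor_id=f"{quad}{mag}",
                    parameters=params,
                    proliferation_offset=sp * pct,
                    diffusion_offset=sd * pct,
                )
            )
    return cohort
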
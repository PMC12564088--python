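import numpy as np
import pytest

from gliopred.grids import Grid, ScalarField
from gliopred.domain import DomainConfig, LesionConfig, build_tissue_domain, \
    synthesize_initial_conditions
from gliopred.cohort import central_parameters


@pytest.fixture(scope="session")
def small_grid():
    """Isotropic 12^3 grid, 0.25 mm voxels."""
    return Grid((12, 12, 12), (0.25, 0.25, 0.25))


@pytest.fixture(scope="session")
def small_domain(small_grid):
    return build_tissue_domain(small_grid, DomainConfig(), seed=7)


@pytest.fixture(scope="session")
def small_initial(small_domain):
    return synthesize_initial_conditions(small_domain, LesionConfig(radius=0.5),
                                         seed=7)


@pytest.fixture(scope="session")
def params():
    return central_parameters()


def gaussian_field(grid, amplitude=0.5, width=0.3, role="tumor_fraction"):
    X, Y, Z = grid.meshgrid()
    cx, cy, cz = grid.center
    r2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
    return ScalarField(grid, amplitude * np.exp(-r2 / (2 * width**2)), role)
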
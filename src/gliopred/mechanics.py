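"""Linear elastic tissue mechanics coupled to tumor growth.

The tumor-cell gradient exerts a body force on the brain parenchyma with
coupling constant lambda_f, and the tissue responds as a linear elastic
isotropic material in quasi-static equilibrium:

    div(sigma) = lambda_f * grad(N_t),   sigma = lam * tr(eps) I + 2 G eps

with the Lame parameter lam = 2 G nu / (1 - 2 nu) carried by a spatially
varying shear modulus G (white vs gray matter) and a global Poisson ratio.
Boundary conditions on the box: zero displacement normal to each face, free
(zero normal derivative) tangential displacement.

The operator is discretized with second-order central differences on the
voxel grid (conservative face-averaged stencils for the same-direction
terms, four-point cross stencils for the mixed terms), assembled as a
sparse matrix and solved by a cached sparse LU factorization — the operator
depends only on the domain, so repeated solves during a simulation reuse
the factors. The resulting von Mises stress exponentially suppresses both
diffusion coefficients: D = D_0 * exp(-gamma * sigma_vm), with gamma
expressed per kPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .grids import Grid, ScalarField
from .domain import TissueDomain

__all__ = [
    "StressState",
    "SolverError",
    "assemble_elasticity",
    "solve_equilibrium",
    "von_mises",
    "stress_modulated_diffusion",
    "PA_PER_KPA",
]

PA_PER_KPA = 1000.0

#: Voigt component order used for strain/stress arrays of shape (6, nx, ny, nz).
VOIGT = ("xx", "yy", "zz", "xy", "xz", "yz")


class SolverError(RuntimeError):
    """Raised when the discrete elasticity system cannot be solved."""


@dataclass
class StressState:
    """Mechanical equilibrium on a grid: displacement, strain, stress, von Mises."""

    grid: Grid
    displacement: np.ndarray  # (3, nx, ny, nz), mm
    strain: np.ndarray  # (6, nx, ny, nz), Voigt order, dimensionless
    stress: np.ndarray  # (6, nx, ny, nz), Voigt order, Pa
    von_mises: ScalarField  # Pa


def _flat(shape, ix, iy, iz):
    return np.ravel_multi_index((ix, iy, iz), shape)


def _clamped_shift(index_arrays, axis, delta, shape):
    """Indices of the neighbor ``delta`` voxels along ``axis``, clamped to the box."""
    out = list(index_arrays)
    out[axis] = np.clip(out[axis] + delta, 0, shape[axis] - 1)
    return tuple(out)


def assemble_elasticity(domain: TissueDomain) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Discrete elasticity operator and the Dirichlet-row mask.

    Returns ``(A, dirichlet)`` where ``A`` is the (3N, 3N) sparse operator
    acting on displacements flattened as ``comp * N + voxel`` (C voxel
    order) and ``dirichlet`` flags rows replaced by identity (zero normal
    displacement on the corresponding box faces).
    """
    grid = domain.grid
    shape = tuple(grid.shape)
    h = grid.spacing
    n = int(np.prod(shape))
    G = domain.shear_modulus.astype(float)
    nu = domain.poisson_ratio
    lam = 2.0 * G * nu / (1.0 - 2.0 * nu)

    ix, iy, iz = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    idx = (ix.ravel(), iy.ravel(), iz.ravel())
    p = _flat(shape, *idx)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(r, c, v):
        rows.append(np.asarray(r))
        cols.append(np.asarray(c))
        vals.append(np.asarray(v))

    def conservative(comp_eq: int, comp_u: int, coeff: np.ndarray, axis: int) -> None:
        """d/dx_a ( coeff * d u / dx_a ) with face-averaged coefficients."""
        row = comp_eq * n + p
        col0 = comp_u * n + p
        inv_h2 = 1.0 / h[axis] ** 2
        for sign in (+1, -1):
            nb = _clamped_shift(idx, axis, sign, shape)
            q = _flat(shape, *nb)
            face = 0.5 * (coeff.ravel() + coeff.ravel()[q])
            w = face * inv_h2
            # clamped neighbor (q == p at the box edge) gives a zero net term
            add(row, comp_u * n + q, w)
            add(row, col0, -w)

    def cross(comp_eq: int, comp_u: int, coeff: np.ndarray, axis_out: int, axis_in: int) -> None:
        """d/dx_a ( coeff * d u / dx_b ), a != b, four-point stencil."""
        row = comp_eq * n + p
        scale = 1.0 / (4.0 * h[axis_out] * h[axis_in])
        for s_out in (+1, -1):
            nb_out = _clamped_shift(idx, axis_out, s_out, shape)
            c_out = coeff.ravel()[_flat(shape, *nb_out)]
            for s_in in (+1, -1):
                nb = _clamped_shift(nb_out, axis_in, s_in, shape)
                q = _flat(shape, *nb)
                add(row, comp_u * n + q, s_out * s_in * scale * c_out)

    lam_2g = lam + 2.0 * G
    for i in range(3):
        conservative(i, i, lam_2g, i)
        for j in range(3):
            if j == i:
                continue
            conservative(i, i, G, j)
            cross(i, j, lam, i, j)  # d/dx_i (lam d u_j / dx_j)
            cross(i, j, G, j, i)  # d/dx_j (G d u_j / dx_i)

    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n, 3 * n),
    ).tocsr()

    dirichlet = np.zeros(3 * n, dtype=bool)
    for i, coord in enumerate((ix, iy, iz)):
        on_face = (coord.ravel() == 0) | (coord.ravel() == shape[i] - 1)
        dirichlet[i * n + p[on_face]] = True
    keep = sparse.diags((~dirichlet).astype(float))
    A = keep @ A + sparse.diags(dirichlet.astype(float))
    return A.tocsc(), dirichlet


_factor_cache: dict = {}


def _domain_key(domain: TissueDomain):
    return (
        tuple(domain.grid.shape),
        tuple(domain.grid.spacing),
        float(domain.poisson_ratio),
        domain.shear_modulus.tobytes(),
    )


def _factorization(domain: TissueDomain):
    key = _domain_key(domain)
    entry = _factor_cache.get(key)
    if entry is None:
        A, dirichlet = assemble_elasticity(domain)
        try:
            lu = splu(A)
        except RuntimeError as exc:  # pragma: no cover - singular systems
            raise SolverError(f"elasticity factorization failed: {exc}") from exc
        entry = (A, dirichlet, lu)
        if len(_factor_cache) > 8:
            _factor_cache.clear()
        _factor_cache[key] = entry
    return entry


def body_force(n_t: ScalarField, lambda_f: float) -> np.ndarray:
    """Body-force components lambda_f * grad(N_t), shape (3, nx, ny, nz), Pa/mm."""
    grads = np.gradient(n_t.values, *n_t.grid.spacing)
    return lambda_f * np.stack(grads)


def solve_equilibrium(
    n_t: ScalarField,
    domain: TissueDomain,
    lambda_f: float,
) -> StressState:
    """Solve mechanical equilibrium for the current tumor field.

    Linear in ``lambda_f`` and invariant under adding a constant to ``N_t``
    (only the gradient enters the force). A spatially uniform tumor field
    yields zero displacement and zero von Mises stress.
    """
    if lambda_f < 0:
        raise ValueError("lambda_f must be >= 0")
    if n_t.values.shape != tuple(domain.grid.shape):
        raise ValueError("tumor field and domain live on different grids")
    grid = domain.grid
    shape = tuple(grid.shape)
    n = int(np.prod(shape))
    A, dirichlet, lu = _factorization(domain)
    b = body_force(n_t, lambda_f).reshape(3 * n)
    b[dirichlet] = 0.0
    u = lu.solve(b)
    if not np.all(np.isfinite(u)):
        raise SolverError("elasticity solve produced non-finite displacements")
    disp = u.reshape(3, *shape)
    strain = _strain(disp, grid)
    stress = _hooke(strain, domain)
    vm = von_mises(stress)
    return StressState(grid, disp, strain, stress, ScalarField(grid, vm, "stress"))


def _strain(disp: np.ndarray, grid: Grid) -> np.ndarray:
    """Symmetric strain tensor (Voigt order) from displacements by central differences."""
    h = grid.spacing
    d = [np.gradient(disp[c], *h) for c in range(3)]  # d[c][axis]
    exx = d[0][0]
    eyy = d[1][1]
    ezz = d[2][2]
    exy = 0.5 * (d[0][1] + d[1][0])
    exz = 0.5 * (d[0][2] + d[2][0])
    eyz = 0.5 * (d[1][2] + d[2][1])
    return np.stack([exx, eyy, ezz, exy, exz, eyz])


def _hooke(strain: np.ndarray, domain: TissueDomain) -> np.ndarray:
    """Isotropic Hooke's law with spatially varying shear modulus."""
    G = domain.shear_modulus
    nu = domain.poisson_ratio
    lam = 2.0 * G * nu / (1.0 - 2.0 * nu)
    tr = strain[0] + strain[1] + strain[2]
    stress = np.empty_like(strain)
    for k in range(3):
        stress[k] = lam * tr + 2.0 * G * strain[k]
    for k in range(3, 6):
        stress[k] = 2.0 * G * strain[k]
    return stress


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises effective stress from a Voigt-ordered symmetric tensor field.

    sigma_vm = sqrt( 1/2 [ (sxx-syy)^2 + (syy-szz)^2 + (szz-sxx)^2 ]
                     + 3 (sxy^2 + sxz^2 + syz^2) ) >= 0,
    zero for hydrostatic states, abs(s) for uniaxial stress s and sqrt(3)*s
    for pure shear s.
    """
    sxx, syy, szz, sxy, sxz, syz = stress
    dev = 0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
    return np.sqrt(dev + 3.0 * (sxy**2 + sxz**2 + syz**2))


def stress_modulated_diffusion(
    d0: float,
    sigma_vm: ScalarField | np.ndarray,
    gamma_stress: float,
    stress_scale: float = PA_PER_KPA,
) -> np.ndarray:
    """Diffusion coefficient field D = D_0 * exp(-gamma * sigma_vm).

    ``sigma_vm`` is in Pa; ``gamma_stress`` is expressed per kPa, so the
    exponent is ``gamma_stress * sigma_vm / stress_scale``. Monotonically
    decreasing in stress; equals ``d0`` wherever the stress vanishes.
    """
    if d0 < 0 or gamma_stress < 0:
        raise ValueError("d0 and gamma_stress must be >= 0")
    vm = sigma_vm.values if isinstance(sigma_vm, ScalarField) else np.asarray(sigma_vm)
    return d0 * np.exp(-gamma_stress * vm / stress_scale)
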
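"""Grid geometry, parameter containers, the virtual cohort and the synthetic
brain/lesion generators."""

import numpy as np
import pytest

from gliopred.grids import Grid, ScalarField, block_mean
from gliopred.cohort import (
    ModelParameters,
    build_virtual_cohort,
    central_parameters,
)
from gliopred.domain import (
    DomainConfig,
    DomainConstructionError,
    LesionConfig,
    SHEAR_MODULUS_GRAY,
    SHEAR_MODULUS_WHITE,
    build_tissue_domain,
    synthesize_initial_conditions,
)


class TestGrid:
    def test_voxel_volume_is_product_of_spacings(self):
        g = Grid((4, 5, 6), (0.125, 0.125, 0.5))
        assert g.voxel_volume == pytest.approx(0.0078125)

    @pytest.mark.parametrize("shape,spacing", [
        ((0, 4, 4), (1, 1, 1)),
        ((4, 4, 4), (0.0, 1, 1)),
        ((4, 4, 4), (-1, 1, 1)),
    ])
    def test_invalid_geometry_rejected(self, shape, spacing):
        with pytest.raises(ValueError):
            Grid(shape, spacing)

    def test_coarsen_refine_roundtrip_preserves_extent_and_centers(self):
        g = Grid((8, 8, 4), (0.25, 0.25, 1.0), origin=(1.0, 2.0, 3.0))
        c = g.coarsen(2)
        assert c.extent == pytest.approx(g.extent)
        assert c.voxel_volume == pytest.approx(8 * g.voxel_volume)
        # coarse voxel centers sit at the centroid of each fine 2-cube
        assert c.axis_coordinates(0)[0] == pytest.approx(
            g.axis_coordinates(0)[:2].mean())
        assert c.refine(2) == g

    def test_field_shape_must_match_grid(self):
        g = Grid((3, 3, 3), (1, 1, 1))
        with pytest.raises(ValueError):
            ScalarField(g, np.zeros((3, 3, 2)))

    def test_block_mean_averages_cubes(self):
        vals = np.arange(8, dtype=float).reshape(2, 2, 2)
        assert block_mean(vals, 2) == pytest.approx(vals.mean())


class TestModelParameters:
    def test_central_values(self):
        p = central_parameters()
        assert (p.D_t0, p.D_v0, p.k_t, p.k_v) == (0.0263, 0.0100, 0.45, 0.25)
        assert (p.theta_min, p.theta_max) == (0.1, 0.9716)
        assert p.nv_thresh == 0.022 and p.k_dv == 0.125 and p.gamma_stress == 0.25

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ModelParameters(k_t=-1.0)
        with pytest.raises(ValueError):
            ModelParameters(theta_min=0.99, theta_max=0.9)
        with pytest.raises(ValueError):
            ModelParameters(nv_thresh=1.5)


class TestVirtualCohort:
    def test_cohort_structure(self):
        cohort = build_virtual_cohort()
        assert len(cohort) == 13
        central = [s for s in cohort
                   if s.proliferation_offset == 0 and s.diffusion_offset == 0]
        assert len(central) == 1 and central[0].tumor_id == "central"
        assert len({s.tumor_id for s in cohort}) == 13

    def test_quadrant1_25pct_values(self):
        cohort = {s.tumor_id: s for s in build_virtual_cohort()}
        q11 = cohort["11"].parameters
        assert q11.k_t == pytest.approx(0.5625)
        assert q11.k_v == pytest.approx(0.3125)
        assert q11.D_t0 == pytest.approx(0.0263 * 1.25)

    def test_quadrant_sign_convention(self):
        cohort = {s.tumor_id: s for s in build_virtual_cohort()}
        # quadrant 2: +proliferation, -diffusion; quadrant 3 the reverse
        assert cohort["23"].parameters.k_t > 0.45 > cohort["33"].parameters.k_t
        assert cohort["23"].parameters.D_t0 < 0.0263 < cohort["33"].parameters.D_t0

    def test_fixed_constants_shared(self):
        for spec in build_virtual_cohort():
            p = spec.parameters
            assert (p.k_dv, p.theta_min, p.theta_max, p.nv_thresh) == \
                (0.125, 0.1, 0.9716, 0.022)

    def test_pure_function(self):
        assert build_virtual_cohort() == build_virtual_cohort()


class TestTissueDomain:
    def test_deterministic_per_seed(self, small_grid):
        a = build_tissue_domain(small_grid, seed=3)
        b = build_tissue_domain(small_grid, seed=3)
        assert np.array_equal(a.tissue_label, b.tissue_label)
        assert np.array_equal(a.shear_modulus, b.shear_modulus)

    def test_shear_map_takes_only_tissue_values(self, small_domain):
        inside = small_domain.shear_modulus[small_domain.brain_mask]
        assert set(np.unique(inside)) <= {SHEAR_MODULUS_GRAY, SHEAR_MODULUS_WHITE}
        labels = set(np.unique(small_domain.tissue_label[small_domain.brain_mask]))
        assert labels == {1, 2}  # both gray and white present

    def test_all_gray_degenerate_config(self, small_grid):
        dom = build_tissue_domain(
            small_grid, DomainConfig(white_inner=0.5, white_outer=0.5), seed=0)
        assert np.all(dom.shear_modulus[dom.brain_mask] == SHEAR_MODULUS_GRAY)

    def test_boundary_margin(self, small_domain):
        m = small_domain.brain_mask
        assert not m[0].any() and not m[-1].any()
        assert not m[:, 0].any() and not m[:, -1].any()
        assert not m[:, :, 0].any() and not m[:, :, -1].any()

    def test_too_small_grid_rejected(self):
        with pytest.raises(DomainConstructionError):
            build_tissue_domain(Grid((3, 3, 3), (1, 1, 1)))


class TestInitialConditions:
    def test_peak_and_bounds(self):
        # odd shape puts a voxel exactly at the lesion center
        grid = Grid((13, 13, 13), (0.25, 0.25, 0.25))
        domain = build_tissue_domain(grid, seed=0)
        n_t, n_v = synthesize_initial_conditions(
            domain, LesionConfig(radius=0.5), seed=0)
        assert n_t.values.max() == pytest.approx(0.9716, rel=0.01)
        assert n_t.values.min() >= 0 and n_v.values.min() >= 0
        assert np.all(n_t.values[~domain.brain_mask] == 0)
        assert np.all(n_v.values[~domain.brain_mask] == 0)
        # vasculature present within and around the lesion
        assert n_v.values.max() > 0

    def test_zero_radius_lesion_is_empty(self, small_domain):
        n_t, n_v = synthesize_initial_conditions(
            small_domain, LesionConfig(radius=0.0), seed=0)
        assert not n_t.values.any() and not n_v.values.any()

    def test_lesion_mass_matches_analytic_integral(self):
        # fine isotropic grid, sharp-edged plateau: integral ~ peak * 4/3 pi r^3
        grid = Grid((48, 48, 48), (0.1, 0.1, 0.1))
        dom = build_tissue_domain(grid, DomainConfig(brain_semiaxes=(2.0, 2.0, 2.0)),
                                  seed=0)
        cfg = LesionConfig(radius=0.9, edge_width_factor=1 / 18,
                           peak_tumor_fraction=0.8)
        n_t, _ = synthesize_initial_conditions(dom, cfg, seed=0)
        expected = 0.8 * 4.0 / 3.0 * np.pi * 0.9**3
        assert n_t.integral() == pytest.approx(expected, rel=0.05)

    def test_axis_permutation_invariance_for_isotropic_config(self):
        grid = Grid((14, 14, 14), (0.3, 0.3, 0.3))
        dom = build_tissue_domain(grid, DomainConfig(brain_semiaxes=(1.8, 1.8, 1.8),
                                                     white_wobble=0.0), seed=0)
        n_t, n_v = synthesize_initial_conditions(dom, LesionConfig(radius=0.7), seed=0)
        for perm in [(1, 0, 2), (2, 1, 0), (0, 2, 1)]:
            assert np.allclose(n_t.values, np.transpose(n_t.values, perm))
            assert np.allclose(n_v.values, np.transpose(n_v.values, perm))

    def test_oversized_lesion_rejected(self, small_domain):
        with pytest.raises(ValueError):
            synthesize_initial_conditions(small_domain, LesionConfig(radius=50.0))
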
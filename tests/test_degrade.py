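"""SNR / spatial-resolution / temporal-resolution degradation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gliopred.grids import Grid, ScalarField
from gliopred.degrade import (
    SNR_LEVELS,
    TR_SCHEDULES,
    VOXEL_VOLUMES,
    ExperimentCondition,
    add_noise,
    condition_grid,
    condition_manifest,
    degrade,
    resample,
    select_timepoints,
)
from gliopred.growth import TimeCourse


@pytest.fixture
def unit_field():
    grid = Grid((100, 100, 100), (0.2, 0.2, 0.2))
    return ScalarField(grid, np.ones(grid.shape), "tumor_fraction")


def toy_timecourse(days=range(1, 11), shape=(8, 8, 4),
                   spacing=(0.25, 0.25, 1.0), seed=0):
    grid = Grid(shape, spacing)
    rng = np.random.default_rng(seed)
    snaps = {d: (rng.uniform(0, 0.8, shape), rng.uniform(0, 0.1, shape))
             for d in days}
    return TimeCourse(grid, snaps)


class TestAddNoise:
    def test_zeros_preserved(self):
        grid = Grid((5, 5, 5), (1, 1, 1))
        field = ScalarField(grid, np.zeros(grid.shape))
        noisy = add_noise(field, snr=5, seed=0)
        assert not noisy.values.any()

    def test_deterministic_per_seed(self, unit_field):
        a = add_noise(unit_field, 40, seed=9)
        b = add_noise(unit_field, 40, seed=9)
        c = add_noise(unit_field, 40, seed=10)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    @pytest.mark.parametrize("snr", [5, 40, 160])
    def test_empirical_std_is_reciprocal_snr(self, unit_field, snr):
        # clip_max far above 1 so clipping cannot bias the ratio
        noisy = add_noise(unit_field, snr, seed=123, clip_max=10.0)
        ratio = noisy.values.ravel()  # clean field is 1 everywhere
        n = ratio.size
        assert ratio.std() == pytest.approx(1.0 / snr, rel=5.0 / np.sqrt(n))
        # mean ratio within 3 sigma of 1
        assert abs(ratio.mean() - 1.0) < 3.0 / (snr * np.sqrt(n))

    def test_clipping_keeps_fractions_physical(self, unit_field):
        noisy = add_noise(unit_field, 5, seed=1, clip_max=0.9716)
        assert noisy.values.min() >= 0.0 and noisy.values.max() <= 0.9716

    def test_invalid_snr_rejected(self, unit_field):
        with pytest.raises(ValueError):
            add_noise(unit_field, 0, seed=0)


class TestResample:
    def test_identity_at_same_volume(self):
        grid = Grid((8, 8, 4), (0.25, 0.25, 1.0))  # 0.0625 ~ "0.063"
        field = ScalarField(grid, np.random.default_rng(0).uniform(size=grid.shape))
        out = resample(field, 0.063)
        assert out.grid == grid
        assert np.array_equal(out.values, field.values)

    @pytest.mark.parametrize("target", [0.008, 0.50])
    def test_constant_field_reproduced(self, target):
        grid = Grid((8, 8, 4), (0.25, 0.25, 1.0))
        field = ScalarField(grid, np.full(grid.shape, 0.37))
        out = resample(field, target)
        assert np.allclose(out.values, 0.37)

    def test_downsample_ramp_matches_hand_weights(self):
        # 1-D ramp 0..7 along x; factor-2 trilinear at block centroids
        # averages each adjacent pair: (0.5, 2.5, 4.5, 6.5)
        grid = Grid((8, 2, 2), (0.25, 0.25, 1.0))
        vals = np.broadcast_to(np.arange(8.0)[:, None, None], grid.shape).copy()
        out = resample(ScalarField(grid, vals), 0.50, clip_max=None)
        assert out.values[:, 0, 0] == pytest.approx([0.5, 2.5, 4.5, 6.5])

    def test_round_trip_error_bounded_for_smooth_field(self):
        # widths well above the coarsest voxel pitch (0.5 x 0.5 x 2 mm), as
        # for the study's lesion-scale fields
        grid = Grid((16, 16, 16), (0.25, 0.25, 1.0))
        X, Y, Z = grid.meshgrid()
        cx, cy, cz = grid.center
        vals = 0.8 * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * 1.5**2)
                            - (Z - cz) ** 2 / (2 * 5.0**2))
        field = ScalarField(grid, vals)
        back = resample(resample(field, 0.50), 0.063)
        rel = np.linalg.norm(back.values - vals) / np.linalg.norm(vals)
        assert rel < 0.05

    def test_incompatible_target_rejected(self):
        grid = Grid((5, 5, 5), (0.3, 0.3, 0.3))  # 0.027 mm^3: no integer factor
        with pytest.raises(ValueError):
            resample(ScalarField(grid, np.zeros(grid.shape)), 0.008)


class TestSelectTimepoints:
    def test_schedules_yield_expected_days(self):
        tc = toy_timecourse()
        assert select_timepoints(tc, (1, 5)).days == [1, 5]
        assert select_timepoints(tc, (1, 3, 5)).days == [1, 3, 5]
        assert select_timepoints(tc, (1, 2, 3, 4, 5)).days == [1, 2, 3, 4, 5]

    def test_selecting_all_days_is_identity(self):
        tc = toy_timecourse(days=range(1, 6))
        out = select_timepoints(tc, (1, 2, 3, 4, 5))
        for d in range(1, 6):
            assert np.array_equal(out.snapshots[d][0], tc.snapshots[d][0])

    def test_missing_day_rejected(self):
        tc = toy_timecourse(days=[1, 2, 3])
        with pytest.raises(ValueError):
            select_timepoints(tc, (1, 5))


class TestConditionGrid:
    def test_exactly_54_distinct_conditions(self):
        grid = condition_grid()
        assert len(grid) == 54
        assert len({c.condition_id for c in grid}) == 54
        assert {c.snr for c in grid} == set(SNR_LEVELS)
        assert {c.voxel_volume for c in grid} == set(VOXEL_VOLUMES)
        assert {c.tr_days for c in grid} == set(TR_SCHEDULES)

    def test_manifest_round_trips_settings(self):
        grid = condition_grid(base_seed=100)
        manifest = condition_manifest(grid)
        assert len(manifest) == 54
        entry = manifest[grid[0].condition_id]
        assert entry["snr"] == grid[0].snr
        assert entry["replicate_seed"] == 100

    def test_off_grid_values_rejected(self):
        with pytest.raises(ValueError):
            ExperimentCondition(7, 0.063, (1, 5))
        with pytest.raises(ValueError):
            ExperimentCondition(5, 0.1, (1, 5))
        with pytest.raises(ValueError):
            ExperimentCondition(5, 0.063, (1, 4))


class TestDegrade:
    def test_noiseless_surrogate_only_subsets(self):
        tc = toy_timecourse()
        cond = ExperimentCondition(5, 0.063, (1, 5), replicate_seed=3)
        out = degrade(tc, cond, noiseless=True)
        assert out.days == [1, 5]
        assert np.array_equal(out.snapshots[1][0], tc.snapshots[1][0])

    def test_replicates_differ_only_by_noise(self):
        tc = toy_timecourse()
        cond = ExperimentCondition(10, 0.063, (1, 3, 5), replicate_seed=3)
        a = degrade(tc, cond, replicate=0)
        b = degrade(tc, cond, replicate=1)
        a2 = degrade(tc, cond, replicate=0)
        assert np.array_equal(a.snapshots[1][0], a2.snapshots[1][0])
        assert not np.array_equal(a.snapshots[1][0], b.snapshots[1][0])
        assert a.days == b.days == [1, 3, 5]

    def test_noise_independent_per_day_and_species(self):
        tc = toy_timecourse(seed=5)
        cond = ExperimentCondition(5, 0.063, (1, 3, 5), replicate_seed=8)
        out = degrade(tc, cond, replicate=0)
        f1 = out.snapshots[1][0] / np.where(tc.snapshots[1][0] == 0, 1,
                                            tc.snapshots[1][0])
        f3 = out.snapshots[3][0] / np.where(tc.snapshots[3][0] == 0, 1,
                                            tc.snapshots[3][0])
        assert not np.allclose(f1, f3)

    def test_sr_mismatch_rejected(self):
        tc = toy_timecourse(spacing=(0.125, 0.125, 0.5))  # 0.008 mm^3 course
        cond = ExperimentCondition(5, 0.50, (1, 5))
        with pytest.raises(ValueError):
            degrade(tc, cond)


@given(snr=st.sampled_from(SNR_LEVELS), seed=st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_noise_mean_preserved_property(snr, seed):
    """Without clipping, multiplicative noise is unbiased at any SNR/seed."""
    grid = Grid((12, 12, 12), (1, 1, 1))
    field = ScalarField(grid, np.full(grid.shape, 0.5))
    noisy = add_noise(field, snr, seed=seed, clip_max=np.inf)
    n = field.values.size
    tol = 4.0 * 0.5 / snr / np.sqrt(n)
    assert abs(noisy.values.mean() - 0.5) < tol
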
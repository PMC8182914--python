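"""Margin expansion, ROI metrics, regression and statistical tests."""

import numpy as np
import pytest
from scipy import stats

from mar_evalkit.errors import MetricError, ValidationError
from mar_evalkit.geometry_eval import (
    anova_oneway,
    expand_margin,
    fit_linear,
    mann_whitney_u,
    overlap_ratio,
    rmse_in_roi,
    ssim_in_roi,
)
from mar_evalkit.volume_io import CTVolume, VoxelMask

from _oracles import (
    anova_sums_of_squares,
    lattice_ball_points,
    mann_whitney_exact_enumeration,
    ols_normal_equations,
    rmse_double_loop,
)


def vol_of(data, spacing=(1.0, 1.0, 1.0)):
    return CTVolume(data=np.asarray(data, dtype=float), spacing=spacing)


def mask_of(data, spacing=(1.0, 1.0, 1.0), label="ptv"):
    return VoxelMask(data=np.asarray(data, dtype=bool), label=label, spacing=spacing)


class TestExpandMargin:
    def test_zero_margin_is_identity(self):
        data = np.zeros((8, 8, 8), bool)
        data[3:5, 3:5, 3:5] = True
        ctv = mask_of(data, label="ctv")
        ptv = expand_margin(ctv, 0.0)
        assert np.array_equal(ptv.data, data)
        assert ptv.label == "ptv"

    def test_single_voxel_isotropic_matches_lattice_enumeration(self):
        data = np.zeros((13, 13, 13), bool)
        data[6, 6, 6] = True
        ptv = expand_margin(mask_of(data, label="ctv"), 5.0)
        pts = lattice_ball_points(5.0)
        assert len(pts) == 515
        expected = np.zeros_like(data)
        for k, j, i in pts:
            expected[6 + k, 6 + j, 6 + i] = True
        assert np.array_equal(ptv.data, expected)

    def test_single_voxel_anisotropic_matches_enumeration(self):
        spacing = (2.0, 1.0, 1.0)
        data = np.zeros((9, 13, 13), bool)
        data[4, 6, 6] = True
        ptv = expand_margin(mask_of(data, spacing=spacing, label="ctv"), 5.0)
        expected = np.zeros_like(data)
        for k, j, i in lattice_ball_points(5.0, spacing):
            expected[4 + k, 6 + j, 6 + i] = True
        assert np.array_equal(ptv.data, expected)

    def test_ctv_subset_of_ptv(self):
        rng = np.random.default_rng(0)
        data = rng.random((10, 10, 10)) < 0.1
        ptv = expand_margin(mask_of(data, label="ctv"), 3.0)
        assert not (data & ~ptv.data).any()

    def test_resolution_consistency_of_physical_volume(self):
        # same physical ball expanded at 1 mm and at 0.5 mm spacing: the
        # fine-grid volume lies between the coarse volume eroded/dilated by
        # one coarse voxel shell
        coarse = np.zeros((21, 21, 21), bool)
        coarse[10, 10, 10] = True
        fine = np.zeros((41, 41, 41), bool)
        fine[20, 20, 20] = True
        v_coarse = expand_margin(mask_of(coarse, (1, 1, 1), "ctv"), 5.0)
        v_fine = expand_margin(mask_of(fine, (0.5, 0.5, 0.5), "ctv"), 5.0)
        lo = len(lattice_ball_points(4.0)) * 1.0  # one coarse shell inside
        hi = len(lattice_ball_points(6.0)) * 1.0  # one coarse shell outside
        fine_ml = v_fine.voxel_count() * 0.125
        assert lo <= fine_ml <= hi


class TestRmse:
    def test_identity_is_zero(self):
        v = vol_of(np.random.default_rng(0).normal(0, 100, (6, 6, 6)))
        roi = mask_of(np.ones((6, 6, 6)))
        assert rmse_in_roi(v, v, roi) == 0.0

    def test_two_voxel_hand_computation(self):
        ref = vol_of(np.zeros((1, 1, 2)))
        test = vol_of(np.array([[[3.0, 4.0]]]))
        roi = mask_of(np.ones((1, 1, 2)))
        assert rmse_in_roi(ref, test, roi) == pytest.approx(np.sqrt((9 + 16) / 2))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 200, (16, 16, 16))
        b = rng.normal(0, 200, (16, 16, 16))
        roi = rng.random((16, 16, 16)) < 0.4
        got = rmse_in_roi(vol_of(a), vol_of(b), mask_of(roi))
        assert got == pytest.approx(rmse_double_loop(a, b, roi), abs=1e-10)

    def test_empty_roi_rejected(self):
        v = vol_of(np.zeros((4, 4, 4)))
        with pytest.raises(MetricError):
            rmse_in_roi(v, v, mask_of(np.zeros((4, 4, 4))))


class TestSsim:
    def test_identical_volumes_give_one(self):
        rng = np.random.default_rng(2)
        v = vol_of(rng.normal(40, 15, (3, 32, 32)))
        roi = mask_of(np.ones((3, 32, 32)))
        assert ssim_in_roi(v, v, roi) == pytest.approx(1.0, abs=1e-12)

    def test_constant_pair_closed_form(self):
        # zero-variance windows: only the luminance term remains,
        # (2ab + C1)/(a^2 + b^2 + C1) with a=0, b=100, C1=(0.01*2000)^2
        a = vol_of(np.zeros((1, 32, 32)))
        b = vol_of(np.full((1, 32, 32), 100.0))
        roi = mask_of(np.ones((1, 32, 32)))
        expected = (2 * 0 * 100 + 400.0) / (0**2 + 100**2 + 400.0)
        assert ssim_in_roi(a, b, roi, data_range=2000.0) == pytest.approx(expected, rel=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = vol_of(rng.normal(0, 300, (2, 24, 24)))
        b = vol_of(rng.normal(0, 300, (2, 24, 24)))
        roi = mask_of(rng.random((2, 24, 24)) < 0.5)
        assert ssim_in_roi(a, b, roi) == pytest.approx(ssim_in_roi(b, a, roi), abs=1e-12)

    def test_decreases_with_added_noise(self):
        rng = np.random.default_rng(4)
        base = rng.normal(40, 60, (2, 48, 48))
        roi = mask_of(np.ones((2, 48, 48)))
        values = []
        for sd in (10.0, 60.0, 200.0):
            noisy = base + np.random.default_rng(7).normal(0, sd, base.shape)
            values.append(ssim_in_roi(vol_of(base), vol_of(noisy), roi))
        assert values[0] > values[1] > values[2]

    def test_window_validation(self):
        v = vol_of(np.zeros((1, 8, 8)))
        roi = mask_of(np.ones((1, 8, 8)))
        with pytest.raises(ValidationError):
            ssim_in_roi(v, v, roi, window=4)
        with pytest.raises(ValidationError):
            ssim_in_roi(v, v, roi, window=11)  # larger than the slice


class TestOverlapRatio:
    def test_disjoint_masks_give_zero(self):
        a = np.zeros((4, 8, 8), bool)
        a[0, :2] = True
        b = np.zeros((4, 8, 8), bool)
        b[2, :2] = True
        assert overlap_ratio(mask_of(a, label="corrected_region"), mask_of(b)) == 0.0

    def test_superset_gives_one(self):
        ptv = np.zeros((4, 8, 8), bool)
        ptv[1, 2:5, 2:5] = True
        region = np.ones((4, 8, 8), bool)
        assert overlap_ratio(mask_of(region, label="corrected_region"), mask_of(ptv)) == 1.0

    def test_hand_counted_fraction(self):
        ptv = np.zeros((1, 20, 10), bool)
        ptv[0, :20, :10] = True  # 200 voxels
        region = np.zeros((1, 20, 10), bool)
        region[0, :5, :5] = True  # 25 overlap voxels
        assert overlap_ratio(mask_of(region, label="corrected_region"), mask_of(ptv)) == pytest.approx(0.125)

    def test_empty_ptv_rejected(self):
        with pytest.raises(MetricError):
            overlap_ratio(mask_of(np.ones((2, 2, 2)), label="corrected_region"), mask_of(np.zeros((2, 2, 2))))


class TestFitLinear:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 0.3, 13)
        pts = [(xi, -0.67 * xi + 0.95) for xi in x]
        fit = fit_linear(pts)
        assert fit.slope == pytest.approx(-0.67, abs=1e-12)
        assert fit.intercept == pytest.approx(0.95, abs=1e-12)

    def test_two_points_interpolating_line(self):
        fit = fit_linear([(0.0, 1.0), (2.0, 0.0)])
        assert fit.slope == pytest.approx(-0.5)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.n_points == 2

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        pts = list(zip(rng.random(10), rng.random(10)))
        fit = fit_linear(pts)
        slope, intercept = ols_normal_equations(pts)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValidationError):
            fit_linear([(1.0, 0.0), (1.0, 1.0)])


class TestAnova:
    def test_identical_groups_f_zero_p_one(self):
        groups = [(1.0, 2.0, 3.0)] * 3
        f, p = anova_oneway(groups)
        assert f == 0.0 and p == 1.0

    def test_equal_means_f_zero(self):
        f, _ = anova_oneway([(1.0, 2.0, 3.0), (1.0, 2.0, 3.0)])
        assert f == 0.0

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(m, 1, 5) for m in (0.0, 0.5, 1.5)]
        f, p = anova_oneway(groups)
        f_o, p_o = anova_sums_of_squares(groups)
        assert f == pytest.approx(f_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            anova_oneway([(1.0,), (2.0, 3.0)])


class TestMannWhitney:
    def test_identical_samples_p_near_one(self):
        # ties force the normal approximation; the continuity correction
        # keeps p slightly below 1 at these tiny sizes
        _, p = mann_whitney_u((1.0, 2.0, 3.0), (1.0, 2.0, 3.0))
        assert p > 0.8

    def test_exact_enumeration_small_sample(self):
        u, p = mann_whitney_u((1.0, 2.0), (3.0, 4.0))
        u_o, p_o = mann_whitney_exact_enumeration((1.0, 2.0), (3.0, 4.0))
        assert u == u_o == 0
        assert p == pytest.approx(2.0 / 6.0, abs=1e-12)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_exact_matches_enumeration_random_draws(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 6)
        _, p = mann_whitney_u(a, b)
        _, p_o = mann_whitney_exact_enumeration(a, b)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_enumeration_close_to_normal_approximation(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.8, 1, 6)
        _, p_exact = mann_whitney_exact_enumeration(a, b)
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert abs(p_exact - res.pvalue) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])
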
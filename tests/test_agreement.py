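"""Deming regression, Bland-Altman, compensation, coverage, rank-sum."""

import numpy as np
import pytest

from ezquant.agreement import (AgreementError, CompensationModel,
                               apply_compensation, bland_altman, coverage,
                               deming_fit, fit_compensation, rank_sum_compare,
                               replicate_ci)
from ezquant.phantom import generate_paired_measurements


def perpendicular_ss(x, y, slope, intercept):
    return np.sum((y - slope * x - intercept) ** 2) / (1.0 + slope ** 2)


def deming_grid_oracle(x, y, span=8.0, levels=7, n_grid=81):
    """Brute-force minimiser of summed squared perpendicular distances.

    For a fixed slope the optimal intercept is the centroid condition, so a
    1-D slope grid (iteratively refined to below 1e-7 spacing) suffices and
    stays independent of the closed form under test.
    """
    xm, ym = x.mean(), y.mean()
    center, width = 0.0, span
    for _ in range(levels):
        slopes = center + np.linspace(-width, width, n_grid)
        ss = [perpendicular_ss(x, y, m, ym - m * xm) for m in slopes]
        center = slopes[int(np.argmin(ss))]
        width = 2 * width / (n_grid - 1)
    return center, ym - center * xm


class TestDeming:
    def test_collinear_points_recover_the_line(self):
        fit = deming_fit([1, 2, 3], [3, 5, 7])
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_symmetric_descending_line(self):
        fit = deming_fit([0.0, 0.5, 1.0], [1.0, 0.5, 0.0])
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_perpendicular_minimiser(self):
        rng = np.random.default_rng(42)
        for _ in range(3):
            n = rng.integers(50, 200)
            x = rng.uniform(1, 5, n)
            y = 1.1 * x - 0.2 + rng.normal(0, 0.3, n)
            x = x + rng.normal(0, 0.3, n)
            fit = deming_fit(x, y)
            m, c = deming_grid_oracle(x, y)
            assert fit.slope == pytest.approx(m, abs=1e-6)
            assert fit.intercept == pytest.approx(c, abs=1e-6)

    def test_line_passes_through_centroid(self):
        rng = np.random.default_rng(1)
        x, y = rng.uniform(0, 10, 60), rng.uniform(0, 10, 60)
        fit = deming_fit(x, y)
        assert fit.predict(x.mean()) == pytest.approx(y.mean(), abs=1e-10)

    def test_large_lambda_approaches_ols(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 5, 100)
        y = 2.0 * x + rng.normal(0, 0.5, 100)
        from scipy.stats import linregress
        ols = linregress(x, y)
        fit = deming_fit(x, y, lam=1e9)
        assert fit.slope == pytest.approx(ols.slope, rel=1e-4)
        assert fit.intercept == pytest.approx(ols.intercept, abs=1e-3)

    def test_axis_swap_inverts_slope_at_unit_lambda(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 5, 80)
        y = 1.4 * x + 0.3 + rng.normal(0, 0.4, 80)
        fwd = deming_fit(x, y)
        rev = deming_fit(y, x)
        assert rev.slope == pytest.approx(1.0 / fwd.slope, rel=1e-10)

    def test_r_squared_is_symmetric(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 5, 50)
        y = x + rng.normal(0, 1, 50)
        assert deming_fit(x, y).r_squared == pytest.approx(
            deming_fit(y, x).r_squared, rel=1e-12)

    def test_recovers_generating_line_within_jackknife_error(self):
        df = generate_paired_measurements(
            0, n_per_group_each=(40, 60, 60), method_slope=1.047,
            method_bias=-0.058, noise_sd_each=0.17, seed=11)
        fit = deming_fit(df["mm"], df["am"], ci=True)
        assert abs(fit.slope - 1.047) < 3 * fit.slope_se
        assert abs(fit.intercept - (-0.058)) < 3 * fit.intercept_se

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(AgreementError):
            deming_fit([1, 2], [1, 2])
        with pytest.raises(AgreementError):
            deming_fit([1, 2, 3], [5, 5, 5])  # zero covariance


class TestBlandAltman:
    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        ba = bland_altman(x, x + 0.5)
        assert ba.mean_diff == pytest.approx(0.5)
        assert ba.sd_diff == 0.0
        assert (ba.loa_lo, ba.loa_hi) == (pytest.approx(0.5), pytest.approx(0.5))

    def test_hand_computed_sample_sd(self):
        ba = bland_altman([0.0, 0.0], [-1.0, 1.0])  # diffs {-1, +1}
        assert ba.mean_diff == pytest.approx(0.0)
        assert ba.sd_diff == pytest.approx(np.sqrt(2.0))
        assert ba.loa_hi == pytest.approx(1.96 * np.sqrt(2.0))

    def test_loa_reconstruct_from_mean_and_sd(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 5, 200)
        y = x + rng.normal(0.1, 0.2, 200)
        ba = bland_altman(x, y)
        assert ba.loa_hi - ba.loa_lo == pytest.approx(2 * 1.96 * ba.sd_diff,
                                                      abs=1e-10)
        assert ba.loa_lo <= ba.mean_diff <= ba.loa_hi

    def test_emulated_calibration_geometry(self):
        """A constant 0.09 bias with difference SD near 0.344 reproduces
        limits of agreement close to (-0.59, +0.76) at large n."""
        df = generate_paired_measurements(
            3000, method_bias=0.09, noise_sd_each=0.344 / np.sqrt(2), seed=6)
        ba = bland_altman(df["mm"], df["am"])
        assert ba.mean_diff == pytest.approx(0.09, abs=0.02)
        assert ba.loa_lo == pytest.approx(-0.59, abs=0.05)
        assert ba.loa_hi == pytest.approx(0.76, abs=0.05)

    def test_n1_rejected(self):
        with pytest.raises(AgreementError):
            bland_altman([1.0], [2.0])


class TestCompensation:
    def test_constant_offset_recovered(self):
        x = np.array([1.0, 2.0, 3.0])
        model = fit_compensation(x, x + 0.2)
        assert model.a == pytest.approx(0.2, abs=1e-12)
        assert model.b == pytest.approx(0.0, abs=1e-12)

    def test_zero_disagreement_gives_identity(self):
        x = np.array([1.0, 2.0, 3.0])
        model = fit_compensation(x, x)
        assert (model.a, model.b) == (pytest.approx(0.0), pytest.approx(0.0))
        assert apply_compensation(model, 2.7) == pytest.approx(2.7)

    def test_proportional_bias_detected_and_removed(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(1, 5, 120)
        y = 1.1 * x
        model = fit_compensation(x, y)
        assert model.b > 0
        y_c = apply_compensation(model, y, mm=x)
        refit = fit_compensation(x, y_c)
        assert abs(refit.a) < 1e-8 and abs(refit.b) < 1e-8

    def test_lone_value_round_trip_restores_identity_line(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(1, 5, 150)
        y = 1.1 * x
        model = fit_compensation(x, y)
        fit = deming_fit(x, apply_compensation(model, y))
        assert fit.slope == pytest.approx(1.0, abs=0.02)
        assert fit.intercept == pytest.approx(0.0, abs=0.02)

    def test_mean_bias_subtraction(self):
        assert apply_compensation(CompensationModel(0.2, 0.0), 3.0) == \
            pytest.approx(2.8)


class TestReplicateCI:
    def test_zero_variance(self):
        assert replicate_ci([3.1] * 5) == (pytest.approx(3.1),) * 3

    def test_hand_computed_t_interval(self):
        mean, lo, hi = replicate_ci([1, 2, 3, 4, 5])
        half = 2.7764451052 * 1.5811388301 / np.sqrt(5)
        assert mean == pytest.approx(3.0)
        assert hi - mean == pytest.approx(half, abs=1e-6)
        assert mean - lo == pytest.approx(half, abs=1e-6)

    def test_wider_spread_wider_interval(self):
        _, lo1, hi1 = replicate_ci([3.0, 3.1, 2.9, 3.05, 2.95])
        _, lo2, hi2 = replicate_ci([3.0, 3.5, 2.5, 3.25, 2.75])
        assert hi2 - lo2 > hi1 - lo1

    def test_single_replicate_rejected(self):
        with pytest.raises(AgreementError):
            replicate_ci([3.0])


class TestCoverage:
    def test_values_at_replicate_means_give_full_coverage(self):
        values = {f"u{i}": 3.0 + i for i in range(10)}
        cis = {u: (v - 0.2, v + 0.2) for u, v in values.items()}
        assert coverage(values, cis) == (10, 1.0)

    def test_one_outlier_in_33(self):
        values = {f"u{i:02d}": 3.0 for i in range(33)}
        cis = {u: (2.8, 3.2) for u in values}
        values["u07"] = 3.5  # just outside its interval
        n, frac = coverage(values, cis)
        assert n == 32
        assert frac == pytest.approx(32 / 33)

    def test_id_mismatch_and_empty_are_errors(self):
        with pytest.raises(AgreementError):
            coverage({"a": 1.0}, {"b": (0.0, 2.0)})
        with pytest.raises(AgreementError):
            coverage({}, {})


class TestRankSum:
    def test_identical_small_groups_p_one(self):
        _, p = rank_sum_compare([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_groups_exact_p(self):
        u, p = rank_sum_compare([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3), two-sided

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 40)
        ps = [rank_sum_compare(a, a + shift)[1] for shift in (0.2, 0.6, 1.2)]
        assert ps[0] > ps[1] > ps[2]
        assert ps[2] < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(AgreementError):
            rank_sum_compare([], [1.0])
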
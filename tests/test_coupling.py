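"""Coupling analysis: correlation primitives, sinc upsampling, the lag
scan, Fisher z, group tests and FDR, ROI summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from boldcbf.core import LagGrid, SeparatedTimeseries
from boldcbf.coupling import (
    EmptyROIError,
    InsufficientOverlapError,
    _lag_corr,
    _lagged_corr_all,
    cohens_d,
    compute_coupling,
    fdr_bh,
    fisher_z,
    lagged_rmax,
    one_sample_t,
    pearson_r,
    pearson_r0,
    rmax_minus_r0_contrast,
    roi_extract,
    two_sample_t,
    upsample_sinc,
)
from boldcbf.synth import generate_band_limited_process, sinc_shift

BAND = (0.01, 0.071)
ATANH_HALF = 0.5493061443340548  # atanh(1/2), 30-digit arbitrary precision


class TestPearson:
    def test_perfect_and_anti_correlation(self, rng):
        x = rng.standard_normal(50)
        assert np.isclose(pearson_r(x, x), 1.0)
        assert np.isclose(pearson_r(x, -x), -1.0)

    def test_orthogonal_sinusoids(self):
        t = np.arange(100)
        s = np.sin(2 * np.pi * 3 * t / 100)
        c = np.cos(2 * np.pi * 3 * t / 100)
        assert abs(pearson_r(s, c)) < 1e-10

    def test_fixed_six_point_pair_against_scipy(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0, 7.0])
        y = np.array([2.0, 3.0, 1.0, 9.0, 4.0, 6.0])
        expected = stats.pearsonr(x, y).statistic
        assert np.isclose(pearson_r(x, y), expected, atol=1e-12)

    def test_zero_variance_marked_undefined(self):
        assert np.isnan(pearson_r(np.ones(10), np.arange(10.0)))

    def test_vectorized_matches_loop(self, rng):
        x = rng.standard_normal((4, 3, 20))
        y = rng.standard_normal((4, 3, 20))
        r = pearson_r(x, y)
        for i in range(4):
            for j in range(3):
                assert np.isclose(r[i, j], stats.pearsonr(x[i, j], y[i, j]).statistic)

    def test_r0_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_r0(np.zeros((2, 2, 2, 10)), np.zeros((2, 2, 2, 12)))


class TestUpsampleSinc:
    def test_constant_stays_constant(self):
        out = upsample_sinc(np.full((1, 30), 4.0), 7.0, 0.1)
        assert np.allclose(out, 4.0)

    def test_original_samples_preserved(self):
        x = generate_band_limited_process(45, 7.0, BAND, 1.0, seed=3)
        out = upsample_sinc(x, 7.0, 0.1)
        assert np.allclose(out[::70], x, atol=1e-9)

    def test_interior_matches_analytic_sinusoid(self):
        # 0.03 Hz over 100 samples at dt 7 s = 21 full cycles
        n, dt = 100, 7.0
        t = np.arange(n) * dt
        x = np.sin(2 * np.pi * 0.03 * t)
        out = upsample_sinc(x, dt, 0.1)
        t_up = np.arange(out.size) * 0.1
        expected = np.sin(2 * np.pi * 0.03 * t_up)
        interior = slice(10 * 70, -10 * 70)
        assert np.max(np.abs(out[interior] - expected[interior])) < 1e-2

    def test_invalid_resolution_rejected(self):
        with pytest.raises(ValueError):
            upsample_sinc(np.zeros(10), 0.1, 7.0)


class TestLaggedRmax:
    def test_identical_series_peak_at_zero(self):
        x = generate_band_limited_process(45, 7.0, BAND, 1.0, seed=5)
        xu = upsample_sinc(x, 7.0, 0.1)
        rmax, tau = lagged_rmax(xu, xu)
        assert np.isclose(rmax, 1.0)
        assert tau == 0.0

    @pytest.mark.parametrize("lag", [-1.05, 1.05])
    def test_constructed_shift_recovered(self, lag):
        cbf = generate_band_limited_process(64, 7.0, BAND, 1.0, seed=8)
        bold = sinc_shift(cbf, 7.0, lag)  # bold(t) = cbf(t + lag)
        bu = upsample_sinc(bold, 7.0, 0.1)
        cu = upsample_sinc(cbf, 7.0, 0.1)
        rmax, tau = lagged_rmax(bu, cu)
        assert rmax > 0.99
        assert abs(tau - lag) <= 0.35 + 1e-9

    def test_fast_scan_matches_per_lag_oracle(self, rng):
        b = rng.standard_normal((3, 400))
        c = rng.standard_normal((3, 400))
        shifts = LagGrid(tau_min=-2.8, tau_max=2.8).shifts
        fast = _lagged_corr_all(b, c, shifts)
        slow = np.stack([_lag_corr(b, c, int(s)) for s in shifts], axis=-1)
        assert np.allclose(fast, slow, atol=1e-10)

    def test_rmax_never_below_r0(self, rng):
        b = rng.standard_normal((6, 2000))
        c = rng.standard_normal((6, 2000))
        grid = LagGrid()
        rmax, _ = lagged_rmax(b, c, grid)
        r0 = _lag_corr(b, c, 0)
        assert np.all(rmax >= r0 - 1e-12)

    def test_insufficient_overlap_rejected(self):
        with pytest.raises(InsufficientOverlapError):
            lagged_rmax(np.zeros((1, 75)), np.zeros((1, 75)), LagGrid())

    def test_compute_coupling_guarantees_rmax_ge_r0(self, rng):
        sep = SeparatedTimeseries(
            bold=rng.standard_normal((3, 3, 2, 45)),
            cbf=rng.standard_normal((3, 3, 2, 45)),
            dt=7.0,
        )
        cmap = compute_coupling(sep)
        assert np.all(cmap.rmax >= cmap.r0 - 1e-12)
        assert np.all(np.abs(cmap.tau_star) <= 7.0)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_pinned_value(self):
        assert np.isclose(fisher_z(0.5), ATANH_HALF, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.999))
    def test_odd_function(self, r):
        assert np.isclose(fisher_z(-r), -fisher_z(r), atol=1e-14)

    def test_inverse_identity_on_z_grid(self):
        z = np.linspace(-3, 3, 61)
        assert np.allclose(fisher_z(np.tanh(z)), z, atol=1e-12)

    def test_monotone_increasing(self):
        r = np.linspace(-0.999, 0.999, 201)
        assert np.all(np.diff(fisher_z(r)) > 0)

    def test_degenerate_r_clamped_finite(self):
        assert np.isfinite(fisher_z(1.0))
        assert np.isfinite(fisher_z(-1.0))


class TestGroupTests:
    def test_one_sample_all_zero_maps(self):
        res = one_sample_t(np.zeros((4, 5)))
        assert np.allclose(res.t, 0.0)
        assert np.allclose(res.p, 1.0)

    def test_one_sample_constant_nonzero_undefined(self):
        res = one_sample_t(np.full((4, 3), 0.3))
        assert np.all(np.isnan(res.t))
        assert not res.mask.any()

    def test_one_sample_against_textbook_formula(self):
        vals = np.array([0.1, 0.2, 0.3, 0.2, 0.2])
        res = one_sample_t(vals[:, None])
        mean, sd = vals.mean(), vals.std(ddof=1)
        expected_t = mean / (sd / np.sqrt(5))
        assert np.isclose(res.t[0], expected_t, atol=1e-12)
        ref = stats.ttest_1samp(vals, 0.0)
        assert np.isclose(res.t[0], ref.statistic, atol=1e-12)
        assert np.isclose(res.p[0], ref.pvalue, atol=1e-12)
        assert res.dof == 4

    def test_one_sample_needs_two_subjects(self):
        with pytest.raises(ValueError):
            one_sample_t(np.zeros((1, 5)))

    def test_two_sample_identical_groups_zero(self, rng):
        a = rng.standard_normal((5, 7))
        res = two_sample_t(a, a.copy())
        assert np.allclose(res.t, 0.0)

    def test_two_sample_antisymmetric(self, rng):
        a = rng.standard_normal((5, 7))
        b = rng.standard_normal((6, 7))
        r1 = two_sample_t(a, b)
        r2 = two_sample_t(b, a)
        assert np.allclose(r1.t, -r2.t, atol=1e-12)
        assert np.allclose(r1.p, r2.p, atol=1e-12)

    def test_two_sample_against_scipy(self, rng):
        a = rng.standard_normal((8, 4)) + 0.5
        b = rng.standard_normal((9, 4))
        res = two_sample_t(a, b)
        ref = stats.ttest_ind(a, b, axis=0)
        assert np.allclose(res.t, ref.statistic, atol=1e-12)
        assert np.allclose(res.p, ref.pvalue, atol=1e-12)
        welch = two_sample_t(a, b, welch=True)
        ref_w = stats.ttest_ind(a, b, axis=0, equal_var=False)
        assert np.allclose(welch.t, ref_w.statistic, atol=1e-12)

    def test_null_p_values_uniform(self, rng):
        # 1000 independent voxels under the null: KS against uniform
        a = rng.standard_normal((8, 1000))
        b = rng.standard_normal((8, 1000))
        res = two_sample_t(a, b)
        assert stats.kstest(res.p, "uniform").pvalue > 0.01


class TestFDR:
    def test_all_ones_no_rejections(self):
        reject, q = fdr_bh(np.ones(20))
        assert not reject.any()
        assert np.allclose(q, 1.0)

    def test_hand_evaluated_step_up(self):
        # p_(4) = 0.04 <= 4 * 0.05 / 4 -> all four rejected
        reject, q = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), alpha=0.05)
        assert reject.all()
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_empty_input(self):
        reject, q = fdr_bh(np.array([]))
        assert reject.size == 0 and q.size == 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_q_at_least_p(self, seed):
        p = np.random.default_rng(seed).uniform(size=50)
        _, q = fdr_bh(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)


class TestROI:
    def test_uniform_map_returns_value(self):
        m = np.full((4, 4, 2), 3.5)
        mask = np.zeros((4, 4, 2), bool)
        mask[1:3, 1:3, :] = True
        mean, n = roi_extract(m, mask)
        assert mean == 3.5 and n == 8

    def test_disjoint_gm_support_rejected(self):
        m = np.ones((4, 4, 2))
        mask = np.zeros((4, 4, 2), bool)
        mask[0] = True
        gm = np.zeros((4, 4, 2))
        gm[3] = 1.0
        with pytest.raises(EmptyROIError):
            roi_extract(m, mask, gm, threshold=0.3)

    def test_checkerboard_mean_by_enumeration(self):
        idx = np.indices((4, 4, 2)).sum(axis=0)
        m = (idx % 2).astype(float) * 10.0
        mask = np.ones((4, 4, 2), bool)
        gm = np.full((4, 4, 2), 0.5)
        expected = np.mean([m[i, j, k] for i in range(4) for j in range(4) for k in range(2)])
        mean, n = roi_extract(m, mask, gm)
        assert np.isclose(mean, expected) and n == 32


class TestContrast:
    def test_identical_distributions_zero_effect(self):
        a = np.column_stack([np.r_[0.1, 0.2, 0.3], np.r_[0.2, 0.3, 0.4]])
        res = rmax_minus_r0_contrast(a, a.copy())
        assert res.t == 0.0 and res.d == 0.0

    def test_unit_pooled_sd_gives_d_equal_mean_difference(self):
        s = 1.0 / np.sqrt(2.0)
        a = np.column_stack([np.zeros(2), np.array([1 - s, 1 + s])])  # diffs mean 1
        b = np.column_stack([np.zeros(2), np.array([-s, s])])  # diffs mean 0
        res = rmax_minus_r0_contrast(a, b)
        assert np.isclose(res.d, 1.0, atol=1e-12)
        assert np.isclose(res.mean_a - res.mean_b, 1.0)

    def test_cohens_d_against_definition(self, rng):
        a = rng.standard_normal(10) + 1.0
        b = rng.standard_normal(12)
        pooled = np.sqrt(((9 * a.var(ddof=1)) + 11 * b.var(ddof=1)) / 20)
        assert np.isclose(cohens_d(a, b), (a.mean() - b.mean()) / pooled, atol=1e-12)
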
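"""Separation recipe: filter behaviour, demodulation, crosstalk bounds,
physiological and nuisance regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from boldcbf.core import (
    AcquisitionParams,
    DualEchoPCASLRun,
    InvalidBandError,
    TagError,
)
from boldcbf.coupling import pearson_r
from boldcbf.separation import (
    PhysioCoverageError,
    bandpass,
    nuisance_regress,
    retroicor_regress,
    separate_bold,
    separate_cbf,
    separate_run,
    spatial_smooth,
    split_and_rebuild,
)
from boldcbf.synth import (
    assemble_dual_echo_run,
    generate_band_limited_process,
    make_physio_trace,
    uniform_truth,
)

TR = 3.5


class TestSplitRebuild:
    def test_identity_on_interleaved_run(self, acq, truth, rng):
        run = assemble_dual_echo_run(truth, acq, seed=rng)
        e1, e2 = split_and_rebuild(run)
        assert e1 is run.echo1 and e2 is run.echo2

    def test_non_alternating_tags_rejected(self):
        data = np.zeros((2, 2, 2, 4))
        with pytest.raises(TagError):
            DualEchoPCASLRun(
                echo1=data, echo2=data,
                tags=np.array(["L", "L", "C", "C"]),
                acq=AcquisitionParams(matrix=(2, 2, 2), n_volumes=4),
            )

    def test_split_rebuild_round_trip_bit_identical(self, acq, truth, rng):
        run = assemble_dual_echo_run(truth, acq, seed=rng)
        c = run.echo1[..., 0::2].copy()
        l = run.echo1[..., 1::2].copy()
        rebuilt = np.empty_like(run.echo1)
        rebuilt[..., 0::2] = c
        rebuilt[..., 1::2] = l
        assert np.array_equal(rebuilt, run.echo1)


class TestSeparateCBF:
    def test_constant_input_gives_zero(self):
        out = separate_cbf(np.full((2, 2, 2, 40), 7.0), TR)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_constant_difference_recovered(self):
        # interleave c, l with constant c - l = delta: output ~ delta
        n = 60
        delta = 4.0
        s = np.full(n, 100.0)
        s[1::2] -= delta
        out = separate_cbf(s[None, None, None, :], TR)[0, 0, 0]
        assert np.allclose(out[1:-1], delta, rtol=1e-6)

    def test_label_first_flips_sign_convention(self):
        n = 60
        delta = 4.0
        s = np.full(n, 100.0)
        s[0::2] -= delta  # label first
        out = separate_cbf(s[None, None, None, :], TR, control_first=False)[0, 0, 0]
        assert np.allclose(out[1:-1], delta, rtol=1e-6)

    def test_pure_bold_fluctuation_suppressed(self, rng):
        # in-band slow fluctuation leaks < 1e-3 of its variance
        b = generate_band_limited_process(90, TR, (0.01, 0.071), 1.0, rng)
        s = 1000.0 * (1.0 + 0.01 * b)
        out = separate_cbf(s[None, None, None, :], TR)[0, 0, 0]
        assert out[1:-1].var() / (1000.0 * 0.01 * b).var() < 1e-3

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError):
            separate_cbf(np.zeros((1, 1, 1, 5)), TR)


class TestSeparateBOLD:
    def test_constant_preserved(self):
        out = separate_bold(np.full((1, 1, 1, 40), 3.0), TR)
        assert np.allclose(out, 3.0)

    def test_alternating_component_removed(self):
        n = 90
        d = 5.0
        s = 100.0 + d * np.cos(np.pi * np.arange(n))
        out = separate_bold(s[None, None, None, :], TR)[0, 0, 0]
        assert out[1:-1].std() < 1e-3 * d

    def test_modulated_alternation_suppressed(self, rng):
        # label/control modulation with in-band amplitude fluctuation
        n = 90
        f = generate_band_limited_process(n, TR, (0.01, 0.071), 1.0, rng)
        mod = 5.0 * (1.0 + 0.1 * f) * np.cos(np.pi * np.arange(n))
        out = separate_bold((100.0 + mod)[None, None, None, :], TR)[0, 0, 0]
        assert out[1:-1].var() / mod.var() < 1e-3

    def test_slow_sinusoid_recovered(self):
        n = 200
        t = np.arange(n) * TR
        s = np.sin(2 * np.pi * 0.02 * t)
        out = separate_bold(s[None, None, None, :], TR)[0, 0, 0]
        t_pair = (t[0::2] + t[1::2]) / 2.0
        expected = np.sin(2 * np.pi * 0.02 * t_pair)
        assert pearson_r(out[2:-2], expected[2:-2]) > 0.99


class TestBandpass:
    def test_constant_goes_to_zero(self):
        assert np.allclose(bandpass(np.full((1, 200), 5.0), 7.0), 0.0, atol=1e-10)

    def test_stop_band_attenuation(self):
        t = np.arange(200) * 7.0  # 0.005 Hz = 7 full cycles in 1400 s
        x = np.sin(2 * np.pi * 0.005 * t)
        assert bandpass(x[None], 7.0).std() < 0.05 * x.std()

    def test_pass_band_preserved(self):
        t = np.arange(200) * 7.0
        x = np.sin(2 * np.pi * 0.03 * t)
        out = bandpass(x[None], 7.0)
        assert abs(out.std() - x.std()) / x.std() < 0.05

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(InvalidBandError):
            bandpass(np.zeros((1, 64)), 7.0, band=(0.01, 0.2))


class TestSpatialSmooth:
    def test_zero_fwhm_is_identity(self, rng):
        x = rng.standard_normal((5, 5, 5, 3))
        assert np.array_equal(spatial_smooth(x, 0.0, (1, 1, 1)), x)

    def test_constant_volume_preserved(self):
        x = np.full((8, 8, 8), 2.5)
        assert np.allclose(spatial_smooth(x, 6.0, (3.6, 3.6, 5.0)), 2.5)

    def test_impulse_matches_sampled_gaussian_kernel(self):
        fwhm, vox = 4.0, 2.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / vox
        x = np.zeros((17, 17, 17))
        x[8, 8, 8] = 1.0
        out = spatial_smooth(x, fwhm, (vox, vox, vox))
        radius = int(4 * sigma + 0.5)
        i = np.arange(-radius, radius + 1)
        k1 = np.exp(-(i**2) / (2 * sigma**2))
        k1 /= k1.sum()
        expected = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        core = out[8 - radius: 8 + radius + 1, 8 - radius: 8 + radius + 1, 8 - radius: 8 + radius + 1]
        assert np.allclose(core, expected, atol=1e-6)


class TestNuisanceRegress:
    def test_empty_regressors_identity(self, rng):
        x = rng.standard_normal((2, 2, 2, 20))
        assert np.array_equal(nuisance_regress(x, None), x)
        assert np.array_equal(nuisance_regress(x, np.empty((20, 0))), x)

    def test_series_equal_to_regressor_flattens(self, rng):
        r = rng.standard_normal(50)
        out = nuisance_regress(r[None, None, None, :], r[:, None])
        assert out.std() < 1e-10
        assert np.isclose(out.mean(), r.mean())

    def test_known_mixture_residual_uncorrelated(self, rng):
        n = 1000
        a, b = rng.standard_normal((2, n))
        y = 2.0 * a + 3.0 * b + 0.5 * rng.standard_normal(n)
        out = nuisance_regress(y[None, None, None, :], np.column_stack([a, b]))[0, 0, 0]
        assert abs(pearson_r(out, a)) < 0.01
        assert abs(pearson_r(out, b)) < 0.01

    def test_mean_preserved(self, rng):
        y = rng.standard_normal(40) + 10.0
        r = rng.standard_normal((40, 2))
        out = nuisance_regress(y[None, None, None, :], r)
        assert np.isclose(out.mean(), y.mean())


class TestRetroicor:
    def _physio_and_times(self, n=90):
        times = np.arange(n) * TR + TR / 2
        physio = make_physio_trace(n * TR + TR)
        return physio, times

    def test_cardiac_locked_signal_removed(self):
        physio, times = self._physio_and_times()
        # signal locked to the true cardiac phase (1 Hz -> phase = 2 pi t)
        s = np.sin(2 * np.pi * 1.0 * times)
        out = retroicor_regress(s[None, None, None, :], physio, times)[0, 0, 0]
        assert out.std() / s.std() < 0.05

    def test_unrelated_signal_untouched(self):
        # in-band sinusoid away from every aliased physio frequency
        # (respiratory harmonics alias to 0.014 / 0.029 Hz, cardiac to
        # ~Nyquist); a long series keeps finite-sample overfit negligible
        physio, times = self._physio_and_times(n=600)
        s = np.sin(2 * np.pi * 0.0508 * times)
        out = retroicor_regress(s[None, None, None, :], physio, times)[0, 0, 0]
        assert pearson_r(out, s) > 0.999

    def test_order_zero_identity(self, rng):
        physio, times = self._physio_and_times()
        s = rng.standard_normal((1, 1, 1, 90))
        assert np.array_equal(retroicor_regress(s, physio, times, order=0), s)

    def test_short_trace_rejected(self):
        physio = make_physio_trace(10.0)
        times = np.arange(90) * TR
        with pytest.raises(PhysioCoverageError):
            retroicor_regress(np.zeros((1, 1, 1, 90)), physio, times)


class TestSeparationProperties:
    def test_both_separators_are_linear(self, rng):
        x = rng.standard_normal((2, 2, 2, 40))
        y = rng.standard_normal((2, 2, 2, 40))
        for op in (lambda s: separate_cbf(s, TR), lambda s: separate_bold(s, TR)):
            assert np.allclose(op(2.0 * x + 3.0 * y), 2.0 * op(x) + 3.0 * op(y), atol=1e-9)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=6, max_value=30))
    def test_length_contract(self, n_pairs):
        x = np.zeros((1, 1, 1, 2 * n_pairs))
        assert separate_cbf(x, TR).shape[-1] == n_pairs
        assert separate_bold(x, TR).shape[-1] == n_pairs

    def test_separate_run_end_to_end_recovers_perfusion_series(self, acq):
        # noise-free run: separated CBF correlates > 0.99 with the injected
        # perfusion fluctuation (pair-mean resolution, interior frames)
        truth = uniform_truth(acq.matrix, coupling=0.0, lag=0.0,
                              bold_fluct_amplitude=0.0, noise_sd=0.0)
        rng = np.random.default_rng(77)
        run, fields = assemble_dual_echo_run(truth, acq, seed=rng, return_fields=True)
        sep = separate_run(run, fwhm=0.0)
        f = fields["perfusion"]
        f_pair = 0.5 * (f[..., 0::2] + f[..., 1::2])
        r = pearson_r(sep.cbf[..., sep.interior], f_pair[..., sep.interior])
        assert np.all(r > 0.99)
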
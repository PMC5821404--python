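"""DFA and spectral scale-free measure tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from alphacrit import lrtc, synthgen
from alphacrit.lrtc import (
    FluctuationFunction,
    alpha_from_beta,
    dfa,
    dfa_fluctuation,
    dfa_profile,
    envelope_spectrum_auc,
    fit_scaling_exponent,
    log_spaced_windows,
    spectral_exponent,
)
from alphacrit.types import Spectrum


class TestProfile:
    def test_constant_input_gives_zero_profile(self):
        assert np.allclose(dfa_profile(np.full(10, 3.7)), 0)

    def test_hand_computed_example(self):
        # demeaned (1,2,3) -> (-1,0,1); cumulative sum -> (-1,-1,0)
        assert np.allclose(dfa_profile([1.0, 2.0, 3.0]), [-1, -1, 0])

    def test_final_element_telescopes_to_zero(self, rng):
        x = rng.normal(size=10_000) * 5 + 2
        prof = dfa_profile(x)
        assert abs(prof[-1]) < 1e-9 * x.size * x.std()

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            dfa_profile([1.0, np.nan, 2.0])


class TestWindows:
    def test_defaults_span_3_to_50_seconds(self):
        w = log_spaced_windows(rate=250.0)
        assert w.size == 15 and w[0] == 750 and w[-1] == 12500
        # at unit rate (beat-count windows) rounding collapses one duplicate
        w1 = log_spaced_windows(rate=1.0)
        assert w1[0] == 3 and w1[-1] == 50 and w1.size >= 14

    def test_count_two_gives_endpoints(self):
        w = log_spaced_windows(5, 40, count=2, rate=10)
        assert list(w) == [50, 400]

    def test_geometric_spacing(self):
        w = log_spaced_windows(3, 50, 15, rate=250.0)
        ratios = w[1:] / w[:-1]
        assert np.all(np.abs(ratios - ratios.mean()) < 0.02 * ratios.mean())


class TestFluctuation:
    def test_zero_profile_gives_zero_fluctuation(self):
        ff = dfa_fluctuation(np.zeros(1000), np.array([10, 20, 50]))
        assert np.allclose(ff.mean_fluct, 0)

    def test_white_noise_alpha_near_half(self):
        alphas = []
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=250 * 1000)
            _, fit = dfa(x, rate=250.0)
            alphas.append(fit.alpha)
        assert abs(np.mean(alphas) - 0.5) < 0.03

    def test_colored_noise_alpha_tracks_spectral_slope(self):
        # beta = 0.5 -> alpha = 0.75 through the spectral relation
        ts = synthgen.gen_colored_noise(0.5, 250 * 1000, 250.0, 11)
        _, fit = dfa(ts.samples, rate=250.0)
        assert abs(fit.alpha - 0.75) < 0.05

    def test_matches_naive_double_loop_oracle(self, rng):
        x = rng.normal(size=10_000).cumsum()  # random-walk profile input
        prof = dfa_profile(np.diff(x))
        windows = log_spaced_windows(20, 2000, 10, rate=1.0)
        ff = dfa_fluctuation(prof, windows)
        ref = oracles.naive_dfa_fluctuation(prof, windows)
        assert np.all(np.abs(ff.mean_fluct - ref) <= 1e-10 * np.abs(ref))

    def test_too_large_window_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            ff = dfa_fluctuation(np.zeros(100), np.array([10, 90]))
        assert list(ff.window_samples) == [10]


class TestScalingFit:
    def test_exact_power_law_recovered(self):
        n = np.array([10, 20, 40, 80, 160])
        ff = FluctuationFunction(n, 2.0 * n**0.7, np.ones(5, dtype=int))
        fit = fit_scaling_exponent(ff)
        assert fit.alpha == pytest.approx(0.7, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_scale_invariance_of_alpha(self):
        n = np.array([10, 20, 40, 80])
        f = 1.3 * n**0.62
        a1 = fit_scaling_exponent(FluctuationFunction(n, f, np.ones(4, int))).alpha
        a2 = fit_scaling_exponent(FluctuationFunction(n, 10 * f, np.ones(4, int))).alpha
        assert a1 == pytest.approx(a2)

    def test_degenerate_zero_fluctuation_raises(self):
        ff = FluctuationFunction(np.array([10, 20, 40]), np.array([0.0, 1.0, 2.0]), np.ones(3, int))
        with pytest.raises(ValueError):
            fit_scaling_exponent(ff)

    @settings(deadline=None, max_examples=20)
    @given(
        a=st.floats(0.5, 5.0),
        b=st.floats(-100.0, 100.0),
    )
    def test_alpha_invariant_under_affine_transform(self, a, b):
        x = np.random.default_rng(7).normal(size=20_000)
        _, fit1 = dfa(x, rate=100.0, win_min_s=0.1, win_max_s=10.0)
        _, fit2 = dfa(a * x + b, rate=100.0, win_min_s=0.1, win_max_s=10.0)
        assert fit1.alpha == pytest.approx(fit2.alpha, abs=1e-9)


class TestSpectralExponent:
    def test_flat_spectrum_gives_zero(self):
        sp = Spectrum(np.linspace(1, 50, 200), np.full(200, 2.0))
        assert abs(spectral_exponent(sp, (1, 50))) < 0.05

    def test_colored_noise_ground_truth(self):
        ts = synthgen.gen_colored_noise(1.0, 2**16, 250.0, 3)
        from alphacrit.envelope import multitaper_spectrum

        sp = multitaper_spectrum(ts, window_s=20.0, smoothing_hz=0.5)
        assert spectral_exponent(sp, (0.5, 50.0)) == pytest.approx(1.0, abs=0.1)

    def test_dfa_and_spectral_routes_agree(self):
        # Envelope-free check of beta = 2*alpha - 1 on one realization
        ts = synthgen.gen_colored_noise(0.6, 250 * 1000, 250.0, 21)
        from alphacrit.envelope import multitaper_spectrum

        sp = multitaper_spectrum(ts, window_s=20.0, smoothing_hz=0.5)
        beta = spectral_exponent(sp, (0.2, 40.0))
        _, fit = dfa(ts.samples, rate=250.0)
        assert abs(fit.alpha - alpha_from_beta(beta)) < 0.1


class TestAlphaFromBeta:
    @pytest.mark.parametrize("beta,alpha", [(0.0, 0.5), (1.0, 1.0), (0.7, 0.85)])
    def test_linear_relation(self, beta, alpha):
        assert alpha_from_beta(beta) == pytest.approx(alpha)


class TestSpectrumAUC:
    def test_flat_level_times_width(self):
        sp = Spectrum(np.linspace(0, 10, 101), np.full(101, 3.0))
        assert envelope_spectrum_auc(sp, (2.0, 7.0)) == pytest.approx(15.0)

    def test_linearity_in_power(self):
        f = np.linspace(1, 20, 50)
        p = np.abs(np.sin(f)) + 0.5
        a1 = envelope_spectrum_auc(Spectrum(f, p), (1, 20))
        a2 = envelope_spectrum_auc(Spectrum(f, 2 * p), (1, 20))
        assert a2 == pytest.approx(2 * a1)

    def test_full_band_auc_matches_variance(self, rng):
        from alphacrit.envelope import multitaper_spectrum
        from alphacrit.types import TimeSeries

        x = rng.normal(size=250 * 120)
        sp = multitaper_spectrum(TimeSeries(x, 250.0))
        auc = envelope_spectrum_auc(sp, (sp.frequencies[0], sp.frequencies[-1]))
        assert auc == pytest.approx(x.var(), rel=0.15)
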
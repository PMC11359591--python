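import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import argrelmax

from beebuzz import SpectralConfig, burg_fit, burg_psd, music_pseudospectrum
from beebuzz.exceptions import ConfigError, DegenerateSignalError
from beebuzz.spectral import autocorrelation_matrix, autocovariance

SAMPLE_RATE = 44100
BIN_WIDTH = SAMPLE_RATE / 2 / 512


class TestBurgFit:
    def test_constant_signal_is_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            burg_fit(np.full(1000, 3.7), order=4)

    def test_order_too_large_rejected(self):
        with pytest.raises(ValueError):
            burg_fit(np.arange(10.0), order=10)

    def test_ar1_coefficient_recovery(self, ar1_signal):
        """Burg order-1 fit recovers a1 = -0.9; oracle = Yule-Walker from the
        empirical lag-1 autocorrelation."""
        a, _ = burg_fit(ar1_signal, order=1)
        assert abs(a[0] + 0.9) < 0.02
        x = ar1_signal - ar1_signal.mean()
        yule_walker = -np.dot(x[1:], x[:-1]) / np.dot(x, x)
        assert abs(a[0] - yule_walker) < 0.01

    def test_white_noise_high_order(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 2.0, 50_000)
        a, e = burg_fit(x, order=4)
        assert np.all(np.abs(a) < 0.05)
        assert abs(e - x.var()) / x.var() < 0.05

    @given(seed=st.integers(0, 1000), order=st.integers(1, 12))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_fitted_model_is_stationary(self, seed, order):
        """All poles of 1 + sum a(k) z^-k lie strictly inside the unit circle."""
        rng = np.random.default_rng(seed)
        x = np.cumsum(rng.normal(size=500))  # correlated test signal
        a, e = burg_fit(x, order)
        roots = np.roots(np.concatenate([[1.0], a]))
        assert np.all(np.abs(roots) < 1.0 + 1e-9)
        assert e >= 0


class TestBurgPsd:
    def test_order_zero_is_flat_white_noise_psd(self):
        fv = burg_psd(np.array([]), noise_power=2.5, n_bins=64)
        np.testing.assert_allclose(fv.values, 2.5)

    def test_ar1_value_at_dc(self):
        """PSD(0) = E / (1 - 0.9)^2 = 100 E by direct substitution."""
        fv = burg_psd(np.array([-0.9]), noise_power=3.0, n_bins=512)
        assert fv.values[0] == pytest.approx(300.0, rel=1e-12)

    def test_matches_direct_formula(self):
        """PSD equals E / |1 + sum a_k exp(-j 2 pi f k)|^2 evaluated directly."""
        a = np.array([-0.5, 0.3, -0.1])
        e_m = 1.7
        fv = burg_psd(a, e_m, n_bins=256)
        f = np.arange(256) / 512  # normalized [0, 0.5)
        k = np.arange(1, 4)
        direct = e_m / np.abs(1 + np.exp(-2j * np.pi * np.outer(f, k)) @ a) ** 2
        np.testing.assert_allclose(fv.values, direct, atol=1e-10, rtol=1e-10)

    def test_ar2_resonance_peak_location(self):
        """Complex-conjugate poles near the unit circle at the 260 Hz wingbeat
        angle put the PSD argmax within one bin of 260 Hz."""
        r, theta = 0.998, 2 * np.pi * 260 / SAMPLE_RATE
        a = np.array([-2 * r * np.cos(theta), r * r])
        fv = burg_psd(a, 1.0, n_bins=512)
        assert abs(np.argmax(fv.values) * BIN_WIDTH - 260) <= BIN_WIDTH

    def test_psd_integrates_to_process_variance(self, ar1_signal):
        """Mean of the one-sided PSD over [0, fs/2) equals the variance of the
        AR process within 10% (two-sided symmetry folds into the mean)."""
        a, e = burg_fit(ar1_signal, order=1)
        fv = burg_psd(a, e, n_bins=2048)
        assert abs(fv.values.mean() - ar1_signal.var()) / ar1_signal.var() < 0.10


class TestAutocorrelationMatrix:
    def test_white_noise_structure(self):
        rng = np.random.default_rng(3)
        n, sigma = 100_000, 1.5
        x = rng.normal(0, sigma, n)
        r = autocorrelation_matrix(x, 8)
        tol = 3 / np.sqrt(n) * sigma**2
        np.testing.assert_allclose(np.diag(r), sigma**2, atol=tol)
        off_diag = r[~np.eye(8, dtype=bool)]
        assert np.all(np.abs(off_diag) < tol)

    def test_cosine_power(self):
        t = np.arange(44100) / 44100
        r = autocorrelation_matrix(3.0 * np.cos(2 * np.pi * 1000 * t), 4)
        assert r[0, 0] == pytest.approx(9.0 / 2, rel=1e-3)

    def test_exact_symmetry_and_psd(self):
        rng = np.random.default_rng(4)
        r = autocorrelation_matrix(rng.normal(size=5000), 16)
        np.testing.assert_array_equal(r, r.T)
        assert np.min(np.linalg.eigvalsh(r)) > -1e-10

    def test_autocovariance_matches_direct_estimator(self):
        """FFT-based biased autocovariance equals the np.correlate definition."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=400)
        xc = x - x.mean()
        direct = np.correlate(xc, xc, mode="full")[xc.size - 1 : xc.size + 9] / xc.size
        np.testing.assert_allclose(autocovariance(x, 10), direct, atol=1e-12)


class TestMusic:
    def test_invalid_subspace_dimension_rejected(self):
        with pytest.raises(ConfigError):
            SpectralConfig(music_matrix_size=16, music_signal_dim=16)

    def test_single_sinusoid_peak_within_one_bin(self):
        rng = np.random.default_rng(7)
        t = np.arange(SAMPLE_RATE) / SAMPLE_RATE
        # SNR 10 dB: tone power 0.5, noise variance 0.05
        sig = np.sin(2 * np.pi * 500 * t) + rng.normal(0, np.sqrt(0.05), SAMPLE_RATE)
        config = SpectralConfig(music_matrix_size=64, music_signal_dim=2, log_scale=False)
        fv = music_pseudospectrum(sig, config)
        assert abs(np.argmax(fv.values) * BIN_WIDTH - 500) <= BIN_WIDTH

    def test_two_close_sinusoids_resolved(self):
        """400 and 460 Hz tones at SNR 10 dB give two local maxima, each within
        one bin of the true frequency, on a grid fine enough to separate them."""
        rng = np.random.default_rng(7)
        t = np.arange(SAMPLE_RATE) / SAMPLE_RATE
        sig = (
            np.sin(2 * np.pi * 400 * t)
            + np.sin(2 * np.pi * 460 * t)
            + rng.normal(0, np.sqrt(0.1), SAMPLE_RATE)
        )
        n_bins = 4096
        config = SpectralConfig(
            music_matrix_size=128, music_signal_dim=4, n_freq_bins=n_bins, log_scale=False
        )
        fv = music_pseudospectrum(sig, config)
        bw = SAMPLE_RATE / 2 / n_bins
        peaks = argrelmax(fv.values)[0]
        top2 = sorted(sorted(peaks, key=lambda i: -fv.values[i])[:2])
        assert abs(top2[0] * bw - 400) <= bw
        assert abs(top2[1] * bw - 460) <= bw

    def test_white_noise_flat_pseudospectrum(self):
        rng = np.random.default_rng(8)
        noise = rng.normal(size=SAMPLE_RATE)
        config = SpectralConfig(music_matrix_size=64, music_signal_dim=0, log_scale=False)
        fv = music_pseudospectrum(noise, config)
        assert fv.values.max() / fv.values.min() < 2.0

    def test_amplitude_scaling_invariance(self):
        rng = np.random.default_rng(9)
        t = np.arange(SAMPLE_RATE) / SAMPLE_RATE
        sig = np.sin(2 * np.pi * 700 * t) + 0.1 * rng.normal(size=SAMPLE_RATE)
        config = SpectralConfig(music_matrix_size=64, music_signal_dim=2, log_scale=False)
        base = music_pseudospectrum(sig, config).values
        scaled = music_pseudospectrum(25.0 * sig, config).values
        ratio = scaled / base
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-6)

    def test_noiseless_sinusoids_produce_divergent_peaks(self):
        """Rank-deficient correlation matrix: pseudospectrum peaks tower over
        the noise-subspace floor by far more than 100x."""
        t = np.arange(SAMPLE_RATE) / SAMPLE_RATE
        f1, f2 = 20 * BIN_WIDTH, 60 * BIN_WIDTH  # exactly on evaluation bins
        sig = np.sin(2 * np.pi * f1 * t) + np.sin(2 * np.pi * f2 * t)
        config = SpectralConfig(music_matrix_size=64, music_signal_dim=4, log_scale=False)
        fv = music_pseudospectrum(sig, config)
        assert fv.values.max() > 100 * np.median(fv.values)
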
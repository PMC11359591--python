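import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beebuzz import AudioSegment, CepstralConfig, gtcc, mfcc
from beebuzz.cepstral import (
    cepstral_dct,
    erb_bandwidth,
    filterbank_energies,
    gammatone_filterbank,
    gammatone_response,
    hz_to_mel,
    mel_filterbank,
    mel_to_hz,
)
from beebuzz.exceptions import ConfigError

SAMPLE_RATE = 44100


def brute_force_dct(log_y, n_coeffs):
    """Independent double-loop evaluation of the cepstral cosine transform."""
    m_count = len(log_y)
    out = np.zeros(n_coeffs)
    for i in range(1, n_coeffs + 1):
        acc = 0.0
        for m in range(1, m_count + 1):
            acc += log_y[m - 1] * np.cos((2 * m - 1) * i * np.pi / (2 * m_count))
        out[i - 1] = np.sqrt(2.0 / m_count) * acc
    return out


class TestMelScale:
    def test_zero_maps_to_zero(self):
        assert hz_to_mel(0.0) == 0.0

    def test_700_hz_reference_point(self):
        assert hz_to_mel(700.0) == pytest.approx(1127.0 * np.log(2.0), rel=1e-12)

    @pytest.mark.parametrize("f", [100.0, 1000.0, 3000.0])
    def test_inverse_round_trip(self, f):
        assert mel_to_hz(hz_to_mel(f)) == pytest.approx(f, rel=1e-9)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            hz_to_mel(-1.0)

    @given(st.floats(0.0, 20000.0), st.floats(0.0, 20000.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_increasing(self, f1, f2):
        lo, hi = sorted((f1, f2))
        assert hz_to_mel(lo) <= hz_to_mel(hi)


class TestMelFilterbank:
    def test_rows_sum_positive_and_centers_nondecreasing(self):
        config = CepstralConfig()
        bank = mel_filterbank(config, SAMPLE_RATE)
        assert bank.shape == (120, 1025)
        assert np.all(bank >= 0)
        assert np.all(bank.sum(axis=1) > 0)
        assert np.all(np.diff(np.argmax(bank, axis=1)) >= 0)

    def test_three_filter_centers_equally_spaced_on_mel(self):
        config = CepstralConfig(n_filters=3, n_coeffs=3, fmin=0.0, fmax=22050.0)
        bank = mel_filterbank(config, SAMPLE_RATE)
        bin_hz = SAMPLE_RATE / config.n_fft
        expected_centers = mel_to_hz(hz_to_mel(22050.0) * np.array([1, 2, 3]) / 4)
        peak_hz = np.argmax(bank, axis=1) * bin_hz
        np.testing.assert_allclose(peak_hz, expected_centers, atol=bin_hz)

    def test_overfine_filterbank_rejected(self):
        config = CepstralConfig(n_filters=120, fmin=50.0, fmax=120.0, n_coeffs=3)
        with pytest.raises(ConfigError):
            mel_filterbank(config, SAMPLE_RATE)


class TestCepstralDct:
    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        log_y = rng.uniform(-5, 5, 24)
        np.testing.assert_allclose(
            cepstral_dct(log_y, 24), brute_force_dct(log_y, 24), atol=1e-10
        )

    def test_matches_scipy_dct_ii(self):
        """The transform is the unnormalised scipy DCT-II scaled by
        sqrt(2/M)/2, at indices 1..n (index 0 dropped)."""
        from scipy.fft import dct as scipy_dct

        rng = np.random.default_rng(6)
        log_y = rng.uniform(-3, 3, 40)
        reference = scipy_dct(log_y, type=2, norm=None) * np.sqrt(2 / 40) / 2
        np.testing.assert_allclose(cepstral_dct(log_y, 39), reference[1:40], atol=1e-10)


class TestMfcc:
    def test_identical_frames_give_identical_coefficients(self):
        block = np.random.default_rng(1).uniform(-0.5, 0.5, 1024)
        seg = AudioSegment(samples=np.tile(block, 8), sample_rate=SAMPLE_RATE)
        config = CepstralConfig(frame_len=1024, hop=1024, n_fft=1024, n_filters=40, n_coeffs=40)
        bank = mel_filterbank(config, SAMPLE_RATE)
        energies = filterbank_energies(seg.samples, bank, config)
        per_frame = cepstral_dct(np.log10(energies), config.n_coeffs)
        assert np.ptp(per_frame, axis=0).max() < 1e-12
        np.testing.assert_allclose(mfcc(seg, config).values, per_frame[0], atol=1e-12)

    def test_gain_shifts_coefficients_by_constant_log_term(self):
        """Scaling the signal by g scales Y(m) by g^2, so every frame's DCT
        input shifts by 2 log10 g and coefficient i changes by
        2 log10(g) sqrt(2/M) sum_m cos((2m-1) i pi / 2M)."""
        seg = AudioSegment(
            samples=np.sin(2 * np.pi * 440 * np.arange(4096) / SAMPLE_RATE),
            sample_rate=SAMPLE_RATE,
        )
        config = CepstralConfig(n_filters=30, n_coeffs=30, fmax=8000.0)
        g = 3.5
        scaled = AudioSegment(samples=g * seg.samples, sample_rate=SAMPLE_RATE)
        delta = mfcc(scaled, config).values - mfcc(seg, config).values
        m = np.arange(1, 31)
        i = np.arange(1, 31)
        cos_sums = np.cos(np.outer(2 * m - 1, i) * np.pi / 60).sum(axis=0)
        expected = 2 * np.log10(g) * np.sqrt(2 / 30) * cos_sums
        np.testing.assert_allclose(delta, expected, atol=1e-8)

    def test_white_noise_first_coefficient_dominates_high_orders(self):
        config = CepstralConfig()
        c1, c_high = [], []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            seg = AudioSegment(samples=rng.normal(0, 0.2, 8192), sample_rate=SAMPLE_RATE)
            values = mfcc(seg, config).values
            c1.append(abs(values[0]))
            c_high.append(np.mean(np.abs(values[60:])))
        assert np.mean(c1) > np.mean(c_high)

    def test_deterministic(self, small_corpus):
        seg = small_corpus[0]
        np.testing.assert_array_equal(mfcc(seg).values, mfcc(seg).values)

    def test_short_segment_rejected(self):
        seg = AudioSegment(samples=np.zeros(100), sample_rate=SAMPLE_RATE)
        with pytest.raises(ValueError):
            mfcc(seg)


class TestGammatone:
    def test_unit_response_at_center(self):
        assert gammatone_response(1000.0, 1000.0, 130.0, order=1) == pytest.approx(1 + 0j)
        assert abs(gammatone_response(1000.0, 1000.0, 130.0, order=4)) == pytest.approx(1.0)

    def test_minus_three_db_at_one_bandwidth_order_one(self):
        mag = abs(gammatone_response(1130.0, 1000.0, 130.0, order=1))
        assert 20 * np.log10(mag) == pytest.approx(-3.0103, abs=1e-3)

    @given(st.floats(1.0, 5000.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_magnitude_symmetry_about_center(self, delta):
        f0, bw = 2000.0, 240.0
        up = abs(gammatone_response(f0 + delta, f0, bw, order=4))
        down = abs(gammatone_response(f0 - delta, f0, bw, order=4))
        assert up == pytest.approx(down, rel=1e-12)


class TestGtcc:
    def test_filter_peaks_at_bin_nearest_center(self):
        from beebuzz.cepstral import erb_rate_to_hz, hz_to_erb_rate

        config = CepstralConfig(n_filters=20, n_coeffs=20)
        bank = gammatone_filterbank(config, SAMPLE_RATE)
        bin_hz = SAMPLE_RATE / config.n_fft
        centers = erb_rate_to_hz(
            np.linspace(hz_to_erb_rate(config.fmin), hz_to_erb_rate(config.fmax), 20)
        )
        np.testing.assert_array_equal(np.argmax(bank, axis=1), np.round(centers / bin_hz))
        # On-grid the response is exactly 1; off-grid it loses at most the
        # half-bin attenuation of the narrowest (lowest) filter.
        half_bin_worst = (1 + (bin_hz / 2 / erb_bandwidth(config.fmin)) ** 2) ** -config.gamma_order
        assert np.all(bank.max(axis=1) >= half_bin_worst - 1e-12)
        assert np.all(bank.max(axis=1) <= 1.0)

    def test_pure_tone_excites_nearest_filter_most(self):
        config = CepstralConfig(n_filters=40, n_coeffs=40)
        bank = gammatone_filterbank(config, SAMPLE_RATE)
        t = np.arange(4096) / SAMPLE_RATE
        energies = filterbank_energies(np.sin(2 * np.pi * 1000 * t), bank, config).mean(axis=0)
        centers_hz = np.argmax(bank, axis=1) * SAMPLE_RATE / config.n_fft
        assert abs(centers_hz[np.argmax(energies)] - 1000) == np.min(np.abs(centers_hz - 1000))

    def test_shares_dimension_and_aggregation_contract_with_mfcc(self, small_corpus):
        seg = small_corpus[0]
        g, m = gtcc(seg), mfcc(seg)
        assert g.dim == m.dim == 120
        assert g.method == "gtcc" and m.method == "mfcc"
        assert g.label == m.label == seg.label

    def test_erb_bandwidth_glasberg_moore(self):
        assert erb_bandwidth(1000.0) == pytest.approx(24.7 * 5.37, rel=1e-12)

    def test_energies_nonnegative_for_arbitrary_input(self):
        rng = np.random.default_rng(12)
        config = CepstralConfig(n_filters=16, n_coeffs=16)
        bank = gammatone_filterbank(config, SAMPLE_RATE)
        energies = filterbank_energies(rng.uniform(-1, 1, 4096), bank, config)
        assert np.all(energies >= 0)
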
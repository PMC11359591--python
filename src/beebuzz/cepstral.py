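"""Cepstral features from mel and gammatone auditory filterbanks.

Both extractors share one pipeline: Hamming-windowed frames, FFT power
spectrum, filterbank energies Y(m), then a cosine transform of log10 Y:

    c_i = sqrt(2/M) * sum_{m=1..M} log10 Y(m) * cos((2m - 1) i pi / (2 M))

for i = 1..n_coeffs. The full transform is kept (n_coeffs = n_filters = 120,
no truncation), so each 1-second segment yields a 120-dimensional vector
after averaging the per-frame coefficients.

The mel filterbank uses triangular filters with centers equally spaced on
the mel scale, mel(f) = 1127 ln(1 + f/700). The gammatone filterbank samples
the magnitude-squared frequency response

    |GT(f)|^2 = |1 + j (f - f0) / BW|^(-2N)

on the FFT grid, with center frequencies equally spaced on the ERB-rate
scale and per-filter bandwidth from the Glasberg-Moore equivalent
rectangular bandwidth, ERB(f0) = 24.7 (4.37 f0 / 1000 + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .audio_io import AudioSegment
from .exceptions import ConfigError
from .features import FeatureVector

#: Energy floor applied before log10 so silent frames stay finite.
ENERGY_FLOOR = 1e-12


@dataclass(frozen=True)
class CepstralConfig:
    """Framing and filterbank settings shared by MFCC and GTCC.

    Defaults: 2048-sample (~46 ms at 44.1 kHz) Hamming frames with 50%
    hop, 120 filters between 50 Hz and 6 kHz — a band bracketing the
    wingbeat fundamental (~260 Hz) and its informative harmonics.
    """

    frame_len: int = 2048
    hop: int = 1024
    n_filters: int = 120
    n_fft: int = 2048
    fmin: float = 50.0
    fmax: float = 6000.0
    n_coeffs: int = 120
    gamma_order: int = 4
    erb_model: str = "glasberg_moore"
    aggregate: str = "mean"

    def __post_init__(self) -> None:
        if self.n_coeffs > self.n_filters:
            raise ConfigError("n_coeffs must be <= n_filters")
        if self.hop > self.frame_len or self.hop <= 0:
            raise ConfigError("require 0 < hop <= frame_len")
        if self.n_fft < self.frame_len:
            raise ConfigError("n_fft must be >= frame_len")
        if not 0 <= self.fmin < self.fmax:
            raise ConfigError("require 0 <= fmin < fmax")
        if self.aggregate not in ("mean", "median"):
            raise ConfigError("aggregate must be 'mean' or 'median'")
        if self.erb_model != "glasberg_moore":
            raise ConfigError("only the glasberg_moore ERB model is implemented")


def hz_to_mel(f):
    """mel(f) = 1127 ln(1 + f/700)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be nonnegative")
    return 1127.0 * np.log1p(f / 700.0)


def mel_to_hz(mel):
    """Inverse of :func:`hz_to_mel`."""
    mel = np.asarray(mel, dtype=np.float64)
    return 700.0 * np.expm1(mel / 1127.0)


def hz_to_erb_rate(f):
    """Glasberg-Moore ERB-rate scale: 21.4 log10(1 + 0.00437 f)."""
    f = np.asarray(f, dtype=np.float64)
    return 21.4 * np.log10(1.0 + 0.00437 * f)


def erb_rate_to_hz(e):
    e = np.asarray(e, dtype=np.float64)
    return (10.0 ** (e / 21.4) - 1.0) / 0.00437


def erb_bandwidth(f0):
    """Glasberg-Moore equivalent rectangular bandwidth at center f0 (Hz)."""
    f0 = np.asarray(f0, dtype=np.float64)
    return 24.7 * (4.37 * f0 / 1000.0 + 1.0)


def mel_filterbank(config: CepstralConfig, sample_rate: float) -> np.ndarray:
    """Triangular mel filters as an (n_filters, n_fft//2 + 1) weight matrix.

    Centers are equally spaced on the mel scale between mel(fmin) and
    mel(fmax); each triangle rises from the previous center and falls to
    the next, so adjacent filters overlap at each other's centers.
    """
    if config.fmax > sample_rate / 2:
        raise ConfigError("fmax exceeds the Nyquist frequency")
    n_bins = config.n_fft // 2 + 1
    freqs = np.arange(n_bins) * sample_rate / config.n_fft
    edges_mel = np.linspace(
        hz_to_mel(config.fmin), hz_to_mel(config.fmax), config.n_filters + 2
    )
    edges_hz = mel_to_hz(edges_mel)
    bank = np.zeros((config.n_filters, n_bins))
    for m in range(config.n_filters):
        lo, center, hi = edges_hz[m], edges_hz[m + 1], edges_hz[m + 2]
        rising = (freqs - lo) / (center - lo)
        falling = (hi - freqs) / (hi - center)
        bank[m] = np.clip(np.minimum(rising, falling), 0.0, None)
        if not bank[m].any():
            raise ConfigError(
                f"filter {m} has no nonzero FFT bin; reduce n_filters or raise n_fft"
            )
    return bank


def gammatone_response(f, f0: float, bw: float, order: int = 4):
    """Complex gammatone frequency response GT(f) = (1 + j(f-f0)/BW)^(-N)."""
    if bw <= 0:
        raise ValueError("bandwidth must be positive")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    f = np.asarray(f, dtype=np.float64)
    return (1.0 + 1j * (f - f0) / bw) ** (-order)


def gammatone_filterbank(config: CepstralConfig, sample_rate: float) -> np.ndarray:
    """|GT(f)|^2 sampled on the FFT grid, centers equally spaced in ERB rate."""
    if config.fmax > sample_rate / 2:
        raise ConfigError("fmax exceeds the Nyquist frequency")
    n_bins = config.n_fft // 2 + 1
    freqs = np.arange(n_bins) * sample_rate / config.n_fft
    centers = erb_rate_to_hz(
        np.linspace(hz_to_erb_rate(config.fmin), hz_to_erb_rate(config.fmax), config.n_filters)
    )
    bank = np.empty((config.n_filters, n_bins))
    for m, f0 in enumerate(centers):
        bank[m] = np.abs(gammatone_response(freqs, f0, float(erb_bandwidth(f0)), config.gamma_order)) ** 2
    return bank


def cepstral_dct(log_energies: np.ndarray, n_coeffs: int) -> np.ndarray:
    """Cosine transform of the log filterbank energies (see module docstring).

    ``log_energies`` may be a vector or an (n_frames, M) matrix; coefficients
    are indexed i = 1..n_coeffs.
    """
    y = np.atleast_2d(np.asarray(log_energies, dtype=np.float64))
    m_count = y.shape[1]
    m = np.arange(1, m_count + 1)
    i = np.arange(1, n_coeffs + 1)
    basis = np.cos(np.outer(2 * m - 1, i) * np.pi / (2 * m_count))  # (M, n_coeffs)
    out = np.sqrt(2.0 / m_count) * y @ basis
    return out if np.asarray(log_energies).ndim == 2 else out[0]


def frame_signal(samples: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """Slice a signal into (n_frames, frame_len) with the given hop."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size < frame_len:
        raise ValueError(f"signal length {x.size} is shorter than one frame ({frame_len})")
    n_frames = 1 + (x.size - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def filterbank_energies(
    samples: np.ndarray, bank: np.ndarray, config: CepstralConfig
) -> np.ndarray:
    """Per-frame filterbank energies Y(m): window, FFT, |X|^2, weight, sum."""
    frames = frame_signal(samples, config.frame_len, config.hop)
    windowed = frames * np.hamming(config.frame_len)
    power = np.abs(np.fft.rfft(windowed, config.n_fft, axis=1)) ** 2
    return power @ bank.T  # (n_frames, n_filters)


def _cepstral_features(segment: AudioSegment, bank: np.ndarray, config: CepstralConfig, method: str) -> FeatureVector:
    energies = filterbank_energies(segment.samples, bank, config)
    if np.any(energies < ENERGY_FLOOR):
        warnings.warn("silent frame: energy floor applied before log10", RuntimeWarning)
        energies = np.maximum(energies, ENERGY_FLOOR)
    coeffs = cepstral_dct(np.log10(energies), config.n_coeffs)
    if config.aggregate == "mean":
        values = coeffs.mean(axis=0)
    else:
        values = np.median(coeffs, axis=0)
    return FeatureVector(values=values, method=method, label=segment.label, source_id=segment.source_id)


def mfcc(segment: AudioSegment, config: CepstralConfig = CepstralConfig()) -> FeatureVector:
    """Mel-frequency cepstral coefficients for one segment (120-dim)."""
    bank = mel_filterbank(config, segment.sample_rate)
    return _cepstral_features(segment, bank, config, "mfcc")


def gtcc(segment: AudioSegment, config: CepstralConfig = CepstralConfig()) -> FeatureVector:
    """Gammatone cepstral coefficients for one segment (120-dim)."""
    bank = gammatone_filterbank(config, segment.sample_rate)
    return _cepstral_features(segment, bank, config, "gtcc")
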
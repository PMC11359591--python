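"""Parametric and subspace spectral features: Burg AR-PSD and MUSIC.

Both estimators summarise a 1-second segment as a 512-bin power vector over
[0, fs/2). The Burg lattice recursion fits an autoregressive model

    x(n) = -sum_k a(k) x(n-k) + e(n)

by minimising the combined forward and backward prediction-error power, and
the PSD is the all-pole spectrum E_m / |1 + sum_k a(k) exp(-j 2 pi f k)|^2.
The MUSIC pseudospectrum eigendecomposes an M x M autocorrelation matrix;
steering vectors orthogonal to the noise subspace produce sharp maxima at
sinusoid frequencies, which suits the harmonic structure of wingbeat buzz.

Feature vectors are reported in dB (10 log10 power) by default so the
sigmoid-ranged autoencoder sees a bounded dynamic range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, toeplitz
from scipy.signal import freqz

from .audio_io import AudioSegment
from .exceptions import ConfigError, DegenerateSignalError
from .features import FeatureVector

#: Floor applied to power values before any log step.
POWER_FLOOR = 1e-30


@dataclass(frozen=True)
class SpectralConfig:
    """Settings for both spectral estimators.

    ar_order : Burg AR model order m. 32 poles are enough to model several
        buzz harmonics below a few kHz while staying stable on 1-s frames.
    n_freq_bins : feature dimension; 512 linear bins over [0, fs/2).
    music_matrix_size : autocorrelation matrix dimension M (M << N). The
        pseudospectrum's resolving power scales like fs/M, so at 44.1 kHz
        M must reach a few hundred before wingbeat fundamentals a few tens
        of Hz apart produce distinct subspaces; M = 256 gives ~172 Hz
        resolution at O(M^3) eigendecomposition cost that is still trivial
        on 1-s frames.
    music_signal_dim : signal-subspace dimension p < M; 16 covers eight
        real sinusoids (fundamental plus harmonics), two eigenvalues each.
    log_scale : emit 10*log10(power) instead of raw power.
    """

    ar_order: int = 32
    n_freq_bins: int = 512
    music_matrix_size: int = 256
    music_signal_dim: int = 16
    log_scale: bool = True

    def __post_init__(self) -> None:
        if self.ar_order <= 0:
            raise ConfigError("ar_order must be positive")
        if self.n_freq_bins <= 0:
            raise ConfigError("n_freq_bins must be positive")
        if not 0 <= self.music_signal_dim < self.music_matrix_size:
            raise ConfigError("require 0 <= music_signal_dim < music_matrix_size")


def burg_fit(samples: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Fit AR coefficients by the Burg lattice recursion.

    Returns ``(a, E)`` where ``a`` holds a(1..m) of the AR polynomial
    ``1 + a(1) z^-1 + ... + a(m) z^-m`` and ``E`` is the final
    prediction-error power. Every reflection coefficient has magnitude <= 1,
    so the fitted model is stationary.
    """
    x = np.asarray(samples, dtype=np.float64)
    if order >= x.size:
        raise ValueError(f"order {order} must be < signal length {x.size}")
    scale = float(np.mean(np.abs(x)))
    x = x - x.mean()
    energy = float(np.dot(x, x)) / x.size
    # Variance at the level of float rounding of the original samples counts
    # as zero (e.g. a constant signal after mean removal).
    if energy <= (1e-12 * scale) ** 2:
        raise DegenerateSignalError("zero-variance signal cannot be fitted")

    # Lattice recursion: f/b are forward/backward prediction errors.
    f = x.copy()
    b = x.copy()
    a = np.zeros(0)
    e = energy
    for m in range(1, order + 1):
        f_tail = f[m:]
        b_head = b[m - 1 : -1]
        denom = float(np.dot(f_tail, f_tail) + np.dot(b_head, b_head))
        if denom == 0.0:
            # Prediction errors vanished: signal exactly AR(m-1); remaining
            # reflection coefficients are zero.
            a = np.concatenate([a, np.zeros(order - m + 1)])
            e = 0.0
            break
        k = -2.0 * float(np.dot(f_tail, b_head)) / denom
        a = np.concatenate([a + k * a[::-1], [k]])
        f_new = f_tail + k * b_head
        b_new = b_head + k * f_tail
        f, b = f_new, b_new
        e *= 1.0 - k * k
    return a, e


def burg_psd(
    ar_coeffs: np.ndarray,
    noise_power: float,
    n_bins: int = 512,
    sample_rate: float = 44100,
    log_scale: bool = False,
) -> FeatureVector:
    """All-pole PSD on ``n_bins`` equally spaced frequencies over [0, fs/2)."""
    a = np.concatenate([[1.0], np.asarray(ar_coeffs, dtype=np.float64)])
    _, h = freqz(1.0, a, worN=n_bins, whole=False, include_nyquist=False)
    psd = noise_power * np.abs(h) ** 2
    if np.any(psd <= POWER_FLOOR) or not np.all(np.isfinite(psd)):
        warnings.warn("PSD clamped to floor at one or more bins", RuntimeWarning)
        psd = np.clip(np.nan_to_num(psd, nan=POWER_FLOOR, posinf=1.0 / POWER_FLOOR), POWER_FLOOR, None)
    values = 10.0 * np.log10(psd) if log_scale else psd
    return FeatureVector(values=values, method="burg")


def autocovariance(samples: np.ndarray, n_lags: int) -> np.ndarray:
    """Biased sample autocovariances r(0..n_lags-1) of the mean-removed signal.

    FFT-based; the biased (divide by n) estimator guarantees a positive
    semi-definite Toeplitz matrix.
    """
    x = np.asarray(samples, dtype=np.float64)
    x = x - x.mean()
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(spec * np.conj(spec), nfft)[:n_lags] / n
    return acov


def autocorrelation_matrix(samples: np.ndarray, size: int) -> np.ndarray:
    """M x M symmetric Toeplitz matrix of biased autocovariances."""
    x = np.asarray(samples, dtype=np.float64)
    if size >= x.size:
        raise ValueError(f"matrix size {size} must be << signal length {x.size}")
    r = autocovariance(x, size)
    return toeplitz(r)


def music_pseudospectrum(
    samples: np.ndarray,
    config: SpectralConfig = SpectralConfig(),
    sample_rate: float = 44100,
) -> FeatureVector:
    """MUSIC pseudospectrum via eigenspace analysis of the correlation matrix.

    The M - p eigenvectors with smallest eigenvalues span the noise
    subspace; the pseudospectrum at frequency f is
    1 / sum_k |e(f)^H v_k|^2 with steering vector
    e(f) = [1, exp(-j 2 pi f), ..., exp(-j 2 pi f (M-1))] (f normalised).
    """
    m = config.music_matrix_size
    p = config.music_signal_dim
    r = autocorrelation_matrix(samples, m)
    eigvals, eigvecs = eigh(r)  # ascending order
    noise = eigvecs[:, : m - p]  # columns spanning the noise subspace
    n_bins = config.n_freq_bins
    f_norm = np.arange(n_bins) / (2 * n_bins)  # [0, 0.5) cycles/sample
    steering = np.exp(-2j * np.pi * np.outer(f_norm, np.arange(m)))
    projections = steering @ noise  # (n_bins, m - p)
    denom = np.sum(np.abs(projections) ** 2, axis=1)
    pseudo = 1.0 / np.maximum(denom, POWER_FLOOR)
    values = 10.0 * np.log10(np.maximum(pseudo, POWER_FLOOR)) if config.log_scale else pseudo
    return FeatureVector(values=values, method="music")


def extract_burg(segment: AudioSegment, config: SpectralConfig = SpectralConfig()) -> FeatureVector:
    """Burg PSD feature for one segment (mean removed, dB by default)."""
    a, e = burg_fit(segment.samples, config.ar_order)
    fv = burg_psd(a, e, config.n_freq_bins, segment.sample_rate, log_scale=config.log_scale)
    return FeatureVector(values=fv.values, method="burg", label=segment.label, source_id=segment.source_id)


def extract_music(segment: AudioSegment, config: SpectralConfig = SpectralConfig()) -> FeatureVector:
    """MUSIC pseudospectrum feature for one segment."""
    fv = music_pseudospectrum(segment.samples, config, segment.sample_rate)
    return FeatureVector(values=fv.values, method="music", label=segment.label, source_id=segment.source_id)
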
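"""Seeded generator of worker/drone-like buzz audio and error samples.

Flight buzz is emulated as a harmonic series on the wingbeat fundamental —
about 260 Hz for workers; drones, being larger with longer wings, are given
a lower default fundamental of 200 Hz (a fixture choice in the biologically
motivated direction, not a field measurement). Each clip applies slow
random frequency jitter, sinusoidal amplitude modulation and additive white
Gaussian noise at a target SNR, then peak-normalises to 0.9.

What this does NOT model: multiple simultaneous bees, Doppler from flight
paths, microphone directivity, wind or colony background hum. Clean
separation between the two synthetic classes is therefore by construction,
and results on these fixtures bound algorithm correctness, not field
performance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .audio_io import AudioSegment
from .autoencoder import ErrorSample
from .exceptions import ConfigError
from .thresholding import GaussianClassModel

#: Worker wingbeat fundamental in Hz (~260 wing beats per second).
WORKER_FUNDAMENTAL_HZ = 260.0
#: Drone fixture fundamental in Hz (lower: larger body, longer wings).
DRONE_FUNDAMENTAL_HZ = 200.0


@dataclass(frozen=True)
class BuzzParams:
    fundamental_hz: float = WORKER_FUNDAMENTAL_HZ
    n_harmonics: int = 8
    harmonic_decay: float = 0.7
    freq_jitter_cents: float = 40.0
    am_depth: float = 0.3
    am_rate_hz: float = 7.0
    snr_db: float | None = 20.0
    duration_s: float = 1.0
    sample_rate: int = 44100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fundamental_hz * self.n_harmonics >= self.sample_rate / 2:
            raise ConfigError("highest harmonic would alias: reduce n_harmonics or f0")
        if not 0 <= self.am_depth <= 1:
            raise ConfigError("am_depth must lie in [0, 1]")
        if self.snr_db is not None and not np.isfinite(self.snr_db):
            raise ConfigError("snr_db must be finite (use None to disable noise)")


def _smooth_jitter(n: int, sample_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Slow jitter track in [-1, 1]: ~4 Hz random control points, interpolated."""
    n_ctrl = max(int(4 * n / sample_rate) + 2, 2)
    ctrl = rng.uniform(-1.0, 1.0, n_ctrl)
    return np.interp(np.linspace(0, n_ctrl - 1, n), np.arange(n_ctrl), ctrl)


def _buzz_components(params: BuzzParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(clean harmonic signal, additive noise) before peak normalisation."""
    n = round(params.duration_s * params.sample_rate)
    t = np.arange(n) / params.sample_rate
    if params.freq_jitter_cents > 0:
        jitter = _smooth_jitter(n, params.sample_rate, rng)
        freq_factor = 2.0 ** (params.freq_jitter_cents * jitter / 1200.0)
    else:
        freq_factor = np.ones(n)
    inst_f0 = params.fundamental_hz * freq_factor
    phase0 = np.cumsum(2 * np.pi * inst_f0 / params.sample_rate)
    clean = np.zeros(n)
    for k in range(1, params.n_harmonics + 1):
        amp = params.harmonic_decay ** (k - 1)
        clean += amp * np.sin(k * phase0 + rng.uniform(0, 2 * np.pi))
    if params.am_depth > 0:
        am_phase = rng.uniform(0, 2 * np.pi)
        clean *= 1.0 - params.am_depth * 0.5 * (1 + np.sin(2 * np.pi * params.am_rate_hz * t + am_phase))
    if params.snr_db is None:
        noise = np.zeros(n)
    else:
        signal_power = np.mean(clean**2)
        noise_power = signal_power / 10.0 ** (params.snr_db / 10.0)
        noise = rng.normal(0.0, np.sqrt(noise_power), n)
    return clean, noise


def generate_buzz(params: BuzzParams, label: str = "unknown", source_id: str = "") -> AudioSegment:
    """One synthetic buzz clip, peak-normalised to 0.9; deterministic per seed."""
    rng = np.random.default_rng(params.seed)
    clean, noise = _buzz_components(params, rng)
    x = clean + noise
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak
    return AudioSegment(
        samples=x,
        sample_rate=params.sample_rate,
        label=label,
        source_id=source_id or f"synthetic:{label}:f0={params.fundamental_hz}:seed={params.seed}",
    )


def generate_dataset(
    n_worker: int,
    n_drone: int,
    worker_params: BuzzParams | None = None,
    drone_params: BuzzParams | None = None,
    seed: int = 0,
) -> list[AudioSegment]:
    """Labelled corpus of independent clips; per-clip seeds derive from ``seed``."""
    if worker_params is None:
        worker_params = BuzzParams(fundamental_hz=WORKER_FUNDAMENTAL_HZ)
    if drone_params is None:
        drone_params = BuzzParams(fundamental_hz=DRONE_FUNDAMENTAL_HZ)
    seed_seq = np.random.SeedSequence(seed)
    clip_seeds = seed_seq.generate_state(n_worker + n_drone) % (2**31)
    segments = []
    for i in range(n_worker):
        p = replace(worker_params, seed=int(clip_seeds[i]))
        segments.append(generate_buzz(p, label="worker", source_id=f"synthetic:worker:{i}"))
    for i in range(n_drone):
        p = replace(drone_params, seed=int(clip_seeds[n_worker + i]))
        segments.append(generate_buzz(p, label="drone", source_id=f"synthetic:drone:{i}"))
    return segments


def generate_error_samples(
    model1: GaussianClassModel,
    model2: GaussianClassModel,
    n1: int,
    n2: int,
    seed: int = 0,
) -> list[ErrorSample]:
    """Seeded Gaussian reconstruction-error draws (truncated at 0) per class.

    Lets the thresholding stage be exercised without audio or training:
    class 1 is labelled worker, class 2 drone.
    """
    rng = np.random.default_rng(seed)
    out = []
    for model, n, label in ((model1, n1, "worker"), (model2, n2, "drone")):
        draws = np.maximum(rng.normal(model.mu, model.sigma, n), 0.0)
        out.extend(
            ErrorSample(mse=float(v), label=label, source_id=f"synthetic-error:{label}:{i}")
            for i, v in enumerate(draws)
        )
    return out
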
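"""WAV input/output and fixed-length segmentation of flight-sound recordings.

Recordings are mono 16-bit PCM WAV sampled at 44,100 Hz; analysis operates on
1-second segments. Multichannel files are mixed down to mono by channel
averaging, and recordings at other sample rates are brought to the reference
rate by polyphase resampling so the frequency-bin layout of every downstream
feature is fixed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .exceptions import AudioFormatError

#: Reference sampling rate of the recording hardware (Hz).
REFERENCE_RATE = 44100

#: Valid class labels for a segment.
LABELS = ("worker", "drone", "unknown")

_INT16_FULL_SCALE = 32768.0


@dataclass(frozen=True)
class AudioSegment:
    """A fixed-rate audio vector with an optional class label.

    Parameters
    ----------
    samples : ndarray
        Real-valued amplitudes, nominally in [-1, 1].
    sample_rate : int
        Sampling rate in Hz.
    label : str
        One of ``worker``, ``drone``, ``unknown``.
    source_id : str
        Provenance string (file path, generator tag, ...).
    """

    samples: np.ndarray
    sample_rate: int
    label: str = "unknown"
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def with_label(self, label: str) -> "AudioSegment":
        return replace(self, label=label)


def read_wav(path: str | os.PathLike) -> AudioSegment:
    """Read a PCM WAV file into an :class:`AudioSegment`.

    Integer samples are scaled to [-1, 1] by division by the type's full
    scale (32768 for 16-bit); multichannel audio is averaged to mono.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise AudioFormatError(f"empty file: {path}")
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise AudioFormatError(f"not a readable PCM WAV file: {path} ({exc})") from exc
    if data.size == 0:
        raise AudioFormatError(f"WAV file contains no samples: {path}")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _INT16_FULL_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported WAV sample format {data.dtype}: {path}")
    if samples.ndim == 2:  # (n_frames, n_channels) -> mono
        samples = samples.mean(axis=1)
    return AudioSegment(samples=samples, sample_rate=int(rate), source_id=str(path))


def write_wav(segment: AudioSegment, path: str | os.PathLike) -> None:
    """Write a segment as 16-bit PCM WAV; samples must lie in [-1, 1]."""
    samples = segment.samples
    if samples.size and np.max(np.abs(samples)) > 1.0 + 1e-12:
        raise ValueError("samples must lie in [-1, 1] before 16-bit quantization")
    quantized = np.clip(np.round(samples * _INT16_FULL_SCALE), -32768, 32767)
    wavfile.write(Path(path), segment.sample_rate, quantized.astype(np.int16))


def resample(segment: AudioSegment, target_rate: int = REFERENCE_RATE) -> AudioSegment:
    """Polyphase-resample a segment to ``target_rate`` (no-op if already there)."""
    if segment.sample_rate == target_rate:
        return segment
    ratio = Fraction(target_rate, segment.sample_rate)
    samples = resample_poly(segment.samples, ratio.numerator, ratio.denominator)
    return AudioSegment(
        samples=samples,
        sample_rate=target_rate,
        label=segment.label,
        source_id=segment.source_id,
    )


def segment(audio: AudioSegment, duration_s: float = 1.0) -> list[AudioSegment]:
    """Cut audio into consecutive non-overlapping windows of ``duration_s``.

    A trailing remainder shorter than one window is discarded; an input
    shorter than one window yields an empty list. Label and source_id
    propagate to every window.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    window = round(duration_s * audio.sample_rate)
    n_windows = audio.samples.size // window
    out = []
    for i in range(n_windows):
        out.append(
            AudioSegment(
                samples=audio.samples[i * window : (i + 1) * window],
                sample_rate=audio.sample_rate,
                label=audio.label,
                source_id=f"{audio.source_id}#{i}" if audio.source_id else f"#{i}",
            )
        )
    return out


def load_dataset(
    root: str | os.PathLike,
    duration_s: float = 1.0,
    target_rate: int = REFERENCE_RATE,
) -> list[AudioSegment]:
    """Load a directory tree with class subfolders ``worker/`` and ``drone/``.

    Every WAV found under a class folder is read, resampled to
    ``target_rate``, segmented into ``duration_s`` windows, and labelled
    from its folder name.
    """
    root = Path(root)
    segments: list[AudioSegment] = []
    for label in ("worker", "drone"):
        folder = root / label
        if not folder.is_dir():
            continue
        for path in sorted(folder.rglob("*.wav")):
            audio = resample(read_wav(path), target_rate).with_label(label)
            segments.extend(segment(audio, duration_s))
    return segments
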
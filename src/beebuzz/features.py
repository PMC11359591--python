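"""Shared feature-vector container and CSV persistence.

Each 1-second segment is summarised by one feature vector: 512 spectral
power coefficients (Burg PSD or MUSIC pseudospectrum) or 120 cepstral
coefficients (MFCC or GTCC).
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

METHODS = ("burg", "music", "mfcc", "gtcc")


@dataclass(frozen=True)
class FeatureVector:
    """One per-segment frequency-domain representation."""

    values: np.ndarray
    method: str
    label: str = "unknown"
    source_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("feature values must be one-dimensional")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")

    @property
    def dim(self) -> int:
        return self.values.size


def feature_matrix(features: list[FeatureVector]) -> np.ndarray:
    """Stack features into an (n_segments, dim) array."""
    if not features:
        raise ValueError("empty feature list")
    dims = {f.dim for f in features}
    if len(dims) != 1:
        raise ValueError(f"inconsistent feature dimensions: {sorted(dims)}")
    return np.vstack([f.values for f in features])


def save_features_csv(features: list[FeatureVector], path: str | os.PathLike) -> None:
    """Persist features as CSV: source_id, label, method, v0, v1, ..."""
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        for f in features:
            writer.writerow([f.source_id, f.label, f.method, *f.values.tolist()])


def load_features_csv(path: str | os.PathLike) -> list[FeatureVector]:
    features = []
    with open(Path(path), newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            source_id, label, method, *values = row
            features.append(
                FeatureVector(
                    values=np.array([float(v) for v in values]),
                    method=method,
                    label=label,
                    source_id=source_id,
                )
            )
    return features
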
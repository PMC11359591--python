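"""Configuration-driven orchestration: extract -> train -> threshold ->
classify -> evaluate, producing a per-cell accuracy/F1 report.

A full experiment sweeps feature methods x encoder depths x thresholds
(up to 4 x 4 x 4 = 64 cells) over one corpus, mirroring the layout of a
method-comparison table. Every report embeds the master seed, a config
hash and library versions so a rerun is reproducible bit-for-bit in
single-threaded execution.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import scipy

from . import __version__
from .audio_io import AudioSegment, load_dataset
from .autoencoder import AutoencoderConfig
from .cepstral import CepstralConfig, gtcc, mfcc
from .exceptions import ConfigError
from .features import FeatureVector
from .model import DroneDetector, SplitConfig, THRESHOLD_NAMES
from .spectral import SpectralConfig, extract_burg, extract_music
from .synth import BuzzParams, DRONE_FUNDAMENTAL_HZ, generate_dataset

logger = logging.getLogger("beebuzz")

FEATURE_METHODS = ("burg", "music", "mfcc", "gtcc")


def extract_features(
    segments: list[AudioSegment],
    method: str,
    spectral: SpectralConfig = SpectralConfig(),
    cepstral: CepstralConfig = CepstralConfig(),
) -> list[FeatureVector]:
    """Apply one extraction method to every segment."""
    if method == "burg":
        return [extract_burg(s, spectral) for s in segments]
    if method == "music":
        return [extract_music(s, spectral) for s in segments]
    if method == "mfcc":
        return [mfcc(s, cepstral) for s in segments]
    if method == "gtcc":
        return [gtcc(s, cepstral) for s in segments]
    raise ConfigError(f"unknown feature method {method!r}")


@dataclass(frozen=True)
class RunConfig:
    """Everything one experiment needs; loadable from YAML."""

    data_dir: str | None = None
    output_dir: str = "beebuzz_out"
    methods: tuple[str, ...] = ("music",)
    architectures: tuple[int, ...] = (2,)
    thresholds: tuple[str, ...] = THRESHOLD_NAMES
    spectral: SpectralConfig = SpectralConfig()
    cepstral: CepstralConfig = CepstralConfig()
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    split: SplitConfig = SplitConfig()
    paper_mode: bool = False
    simulate: bool = False
    n_worker: int = 200
    n_drone: int = 100
    snr_db: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in FEATURE_METHODS:
                raise ConfigError(f"unknown feature method {m!r}")
        for a in self.architectures:
            if a not in (1, 2, 3, 4):
                raise ConfigError("architectures must be within 1..4 encoder hidden layers")
        for t in self.thresholds:
            if t not in THRESHOLD_NAMES:
                raise ConfigError(f"unknown threshold {t!r}")
        if not (self.simulate or self.data_dir):
            raise ConfigError("either data_dir or simulate must be set")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("spectral", SpectralConfig), ("cepstral", CepstralConfig), ("split", SplitConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        for key in ("methods", "architectures", "thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _corpus(config: RunConfig) -> list[AudioSegment]:
    if config.simulate:
        logger.info("simulating corpus: %d worker + %d drone clips", config.n_worker, config.n_drone)
        worker_p = BuzzParams(snr_db=config.snr_db)
        drone_p = BuzzParams(fundamental_hz=DRONE_FUNDAMENTAL_HZ, snr_db=config.snr_db)
        return generate_dataset(config.n_worker, config.n_drone, worker_p, drone_p, seed=config.seed)
    return load_dataset(config.data_dir)


def run_experiment(config: RunConfig) -> dict:
    """Run every (method x architecture) cell and report accuracy/F1 per threshold."""
    t0 = time.perf_counter()
    segments = _corpus(config)
    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "versions": {
            "beebuzz": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
        "n_worker": sum(1 for s in segments if s.label == "worker"),
        "n_drone": sum(1 for s in segments if s.label == "drone"),
        "paper_mode": config.paper_mode,
        "cells": {},
    }
    for method in config.methods:
        stage_t = time.perf_counter()
        features = extract_features(segments, method, config.spectral, config.cepstral)
        logger.info("extracted %s features in %.1fs", method, time.perf_counter() - stage_t)
        for n_hidden in config.architectures:
            stage_t = time.perf_counter()
            ae_config = AutoencoderConfig(
                input_dim=features[0].dim,
                n_encoder_hidden=n_hidden,
                epochs=config.epochs,
                batch_size=config.batch_size,
                learning_rate=config.learning_rate,
                seed=config.seed,
            )
            detector = DroneDetector(
                features,
                config=ae_config,
                split=config.split,
                paper_mode=config.paper_mode,
                seed=config.seed,
            )
            results = detector.fit()
            metrics = results.metrics()
            cell_key = f"{method}/NN{n_hidden}"
            report["cells"][cell_key] = {
                t: metrics[t] for t in config.thresholds
            }
            report["cells"][cell_key]["thresholds"] = {
                "t1": results.thresholds.t1,
                "t2": results.thresholds.t2,
                "t3": results.thresholds.t3,
                "t_star": results.thresholds.t_star,
            }
            logger.info("cell %s done in %.1fs", cell_key, time.perf_counter() - stage_t)
    report["wall_time_s"] = time.perf_counter() - t0
    return report


def format_report(report: dict, thresholds: tuple[str, ...] = THRESHOLD_NAMES) -> str:
    """Plain-text table: feature method x architecture x threshold accuracy."""
    lines = [
        f"beebuzz experiment report (seed {report['seed']}, config {report['config_hash']})",
        f"corpus: {report['n_worker']} worker / {report['n_drone']} drone segments",
        "",
        f"{'cell':<14}" + "".join(f"{'acc ' + t:>12}" for t in thresholds)
        + "".join(f"{'F1 ' + t:>12}" for t in thresholds),
    ]
    for cell, data in report["cells"].items():
        row = f"{cell:<14}"
        for t in thresholds:
            row += f"{data[t]['accuracy']:>11.2%} "
        for t in thresholds:
            row += f"{data[t]['f1']:>11.2%} "
        lines.append(row.rstrip())
    return "\n".join(lines)


def save_report(report: dict, output_dir: str | os.PathLike) -> Path:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    json_path.write_text(json.dumps(report, indent=2))
    (out / "report.txt").write_text(format_report(report) + "\n")
    return json_path
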
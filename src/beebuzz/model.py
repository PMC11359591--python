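"""Top-level model surface: one-class drone detector over feature vectors.

:class:`DroneDetector` bundles the whole decision chain — autoencoder
trained on worker-class features, k-sigma and maximum-likelihood thresholds
on its reconstruction error — behind a fit()/results interface.
:class:`DroneDetectorResults` carries the trained network, the threshold
set with its Gaussian class models, the per-split error samples and the
evaluation metrics, and renders a ``summary()`` table.

Split protocol
--------------
Workers: train (default 80%) / threshold-calibration (10%) / evaluation
(10%). Drones: calibration (50%) / evaluation (50%); drones never enter
training. ``paper_mode=True`` collapses calibration into evaluation —
T* is then fitted on the same errors it is judged on (the protocol a
field deployment would avoid, kept for comparability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autoencoder import Autoencoder, AutoencoderConfig, ErrorSample
from .evaluation import ConfusionCounts, accuracy, confusion, f1_score
from .exceptions import ConfigError
from .features import FeatureVector
from .thresholding import ThresholdSet, classify, compute_thresholds

THRESHOLD_NAMES = ("t1", "t2", "t3", "tstar")


@dataclass(frozen=True)
class SplitConfig:
    worker_train: float = 0.8
    worker_calibration: float = 0.1
    worker_eval: float = 0.1
    drone_calibration: float = 0.5
    drone_eval: float = 0.5

    def __post_init__(self) -> None:
        if abs(self.worker_train + self.worker_calibration + self.worker_eval - 1) > 1e-9:
            raise ConfigError("worker split fractions must sum to 1")
        if abs(self.drone_calibration + self.drone_eval - 1) > 1e-9:
            raise ConfigError("drone split fractions must sum to 1")


class DroneDetector:
    """One-class anomaly model discriminating drone from worker features.

    Parameters
    ----------
    features : list of FeatureVector
        Labelled features (worker and drone) of one extraction method.
    config : AutoencoderConfig, optional
        Network configuration; ``input_dim`` is inferred when omitted.
    split : SplitConfig
        Train / calibration / evaluation fractions.
    paper_mode : bool
        Collapse the calibration split into the evaluation split.
    seed : int
        Seeds the split shuffle and (when config is omitted) the network.
    """

    def __init__(
        self,
        features: list[FeatureVector],
        config: AutoencoderConfig | None = None,
        split: SplitConfig = SplitConfig(),
        paper_mode: bool = False,
        seed: int = 0,
    ):
        workers = [f for f in features if f.label == "worker"]
        drones = [f for f in features if f.label == "drone"]
        if len(workers) < 10 or len(drones) < 4:
            raise ValueError("need at least 10 worker and 4 drone features")
        if config is None:
            config = AutoencoderConfig(input_dim=workers[0].dim, seed=seed)
        self.config = config
        self.split = split
        self.paper_mode = paper_mode
        self.seed = seed
        self._workers = workers
        self._drones = drones

    def _split_features(self):
        rng = np.random.default_rng(self.seed)
        workers = [self._workers[i] for i in rng.permutation(len(self._workers))]
        drones = [self._drones[i] for i in rng.permutation(len(self._drones))]
        n_w = len(workers)
        n_train = round(self.split.worker_train * n_w)
        n_cal = round(self.split.worker_calibration * n_w)
        w_train = workers[:n_train]
        w_cal = workers[n_train : n_train + n_cal]
        w_eval = workers[n_train + n_cal :]
        n_d_cal = round(self.split.drone_calibration * len(drones))
        d_cal = drones[:n_d_cal]
        d_eval = drones[n_d_cal:]
        if self.paper_mode:
            w_eval = w_cal + w_eval
            d_eval = drones
            w_cal, d_cal = w_eval, d_eval
        return w_train, w_cal, w_eval, d_cal, d_eval

    def fit(self) -> "DroneDetectorResults":
        """Train the autoencoder, calibrate thresholds, evaluate held-out data."""
        w_train, w_cal, w_eval, d_cal, d_eval = self._split_features()
        net = Autoencoder(self.config).train(w_train)
        train_errors = net.reconstruction_errors(w_train)
        worker_cal_errors = net.reconstruction_errors(w_cal)
        drone_cal_errors = net.reconstruction_errors(d_cal)
        eval_errors = net.reconstruction_errors(w_eval) + net.reconstruction_errors(d_eval)
        thresholds = compute_thresholds(train_errors, worker_cal_errors, drone_cal_errors)
        return DroneDetectorResults(
            model=self,
            network=net,
            thresholds=thresholds,
            train_errors=train_errors,
            calibration_errors=worker_cal_errors + drone_cal_errors,
            eval_errors=eval_errors,
        )


class DroneDetectorResults:
    """Fitted detector: thresholds, error samples, and evaluation metrics."""

    def __init__(
        self,
        model: DroneDetector,
        network: Autoencoder,
        thresholds: ThresholdSet,
        train_errors: list[ErrorSample],
        calibration_errors: list[ErrorSample],
        eval_errors: list[ErrorSample],
    ):
        self.model = model
        self.network = network
        self.thresholds = thresholds
        self.train_errors = train_errors
        self.calibration_errors = calibration_errors
        self.eval_errors = eval_errors

    def predict(self, errors: list[ErrorSample], threshold: str = "tstar") -> list[str]:
        t = self.thresholds.by_name(threshold)
        return [classify(e, t) for e in errors]

    def confusion(self, threshold: str = "tstar") -> ConfusionCounts:
        truth = [e.label for e in self.eval_errors]
        return confusion(truth, self.predict(self.eval_errors, threshold))

    def metrics(self) -> dict[str, dict[str, float]]:
        """Per-threshold evaluation accuracy and F1 on the held-out split."""
        out = {}
        for name in THRESHOLD_NAMES:
            c = self.confusion(name)
            out[name] = {"accuracy": accuracy(c), "f1": f1_score(c)}
        return out

    def classify_feature(self, feature: FeatureVector, threshold: str = "tstar") -> str:
        """Worker/drone decision for a new, unseen feature vector."""
        return classify(self.network.reconstruction_error(feature), self.thresholds.by_name(threshold))

    def summary(self) -> str:
        m = self.metrics()
        t = self.thresholds
        lines = [
            "Drone detector results (worker = positive class)",
            "=" * 56,
            f"architecture          : {self.network.layer_sizes}",
            f"training segments     : {len(self.train_errors)} (worker only)",
            f"evaluation segments   : {len(self.eval_errors)}",
            f"final training loss   : {self.network.training_loss_[-1]:.3e}",
            "-" * 56,
            f"T1 = {t.t1:.6f}  T2 = {t.t2:.6f}  T3 = {t.t3:.6f}",
            f"T* = {t.t_star:.6f}  "
            f"(worker MSE ~ N({t.class1_model.mu:.3e}, {t.class1_model.sigma:.3e}^2), "
            f"drone MSE ~ N({t.class2_model.mu:.3e}, {t.class2_model.sigma:.3e}^2))",
            "-" * 56,
            f"{'threshold':<10}{'accuracy':>12}{'F1-score':>12}",
        ]
        for name in THRESHOLD_NAMES:
            lines.append(f"{name:<10}{m[name]['accuracy']:>11.2%}{m[name]['f1']:>12.2%}")
        return "\n".join(lines)
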
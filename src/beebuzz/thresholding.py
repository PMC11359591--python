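"""Decision thresholds on the reconstruction error.

Two families of thresholds separate the low-error (worker) region from the
high-error (drone) region of the one-dimensional reconstruction-MSE axis:

* k-sigma rules  T_k = mean(MSE_train) + k * std(MSE_train), k = 1, 2, 3,
  computed from worker-class training errors only;
* the maximum-likelihood threshold T*, the point where the prior-weighted
  Gaussian densities fitted to the two classes' error samples intersect —
  an empirical Bayes decision boundary that minimises misclassification
  under the zero-one loss.

A sample is called drone iff its error exceeds the threshold (ties go to
worker, the dominant class).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .autoencoder import ErrorSample
from .exceptions import DegenerateSignalError


@dataclass(frozen=True)
class GaussianClassModel:
    """Gaussian fit of one class's reconstruction-error distribution."""

    mu: float
    sigma: float
    prior: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.prior < 1:
            raise ValueError("prior must be in (0, 1)")

    def weighted_density(self, x) -> np.ndarray:
        """prior * N(x; mu, sigma^2)."""
        x = np.asarray(x, dtype=np.float64)
        z = (x - self.mu) / self.sigma
        return self.prior * np.exp(-0.5 * z * z) / (self.sigma * math.sqrt(2 * math.pi))


@dataclass(frozen=True)
class ThresholdSet:
    """T1-T3 k-sigma thresholds plus the ML threshold and its class models."""

    t1: float
    t2: float
    t3: float
    t_star: float
    class1_model: GaussianClassModel
    class2_model: GaussianClassModel

    def by_name(self, name: str) -> float:
        return {"t1": self.t1, "t2": self.t2, "t3": self.t3, "tstar": self.t_star}[name]

    def to_json(self) -> str:
        return json.dumps(
            {
                "t1": self.t1,
                "t2": self.t2,
                "t3": self.t3,
                "t_star": self.t_star,
                "class1_model": asdict(self.class1_model),
                "class2_model": asdict(self.class2_model),
            },
            indent=2,
        )


def _mse_array(errors: list[ErrorSample]) -> np.ndarray:
    return np.array([e.mse for e in errors], dtype=np.float64)


def ksigma_threshold(train_errors: list[ErrorSample], k: int) -> float:
    """T_k = mean + k * std of worker-class training errors (sample std, n-1).

    Drone-labelled samples are ignored: the rule is defined on the
    training (worker) reconstruction errors only.
    """
    train_errors = [e for e in train_errors if e.label != "drone"]
    if len(train_errors) < 2:
        raise ValueError("need at least 2 worker training error samples")
    mse = _mse_array(train_errors)
    return float(mse.mean() + k * mse.std(ddof=1))


def fit_gaussian(errors: list[ErrorSample], prior: float = 0.5) -> GaussianClassModel:
    """Sample-mean / sample-std (n-1) Gaussian fit of error samples."""
    if len(errors) < 2:
        raise ValueError("need at least 2 error samples")
    mse = _mse_array(errors)
    sigma = float(mse.std(ddof=1))
    # Spread at the level of float rounding counts as zero variance.
    if sigma <= 1e-12 * max(abs(float(mse.mean())), 1e-300):
        raise DegenerateSignalError("zero-variance error sample: Gaussian fit degenerate")
    return GaussianClassModel(mu=float(mse.mean()), sigma=sigma, prior=prior)


def ml_threshold(class1: GaussianClassModel, class2: GaussianClassModel) -> float:
    """Intersection T* of the prior-weighted class densities in (mu1, mu2).

    Solves prior1 N(x; mu1, s1^2) = prior2 N(x; mu2, s2^2). With equal
    sigmas the closed form is
    (mu1+mu2)/2 + sigma^2 ln(prior1/prior2)/(mu2-mu1); otherwise the
    log-equation is a quadratic in x and the root between the means is
    returned — it is the only root where "higher error implies drone"
    realises the Bayes rule on the dominant interval.
    """
    if not class1.mu < class2.mu:
        raise ValueError("class1 must be the low-error (worker) class")
    mu1, s1, p1 = class1.mu, class1.sigma, class1.prior
    mu2, s2, p2 = class2.mu, class2.sigma, class2.prior
    if math.isclose(s1, s2, rel_tol=1e-12):
        return (mu1 + mu2) / 2 + s1 * s1 * math.log(p1 / p2) / (mu2 - mu1)
    # log p1 - log s1 - (x-mu1)^2 / 2 s1^2 = log p2 - log s2 - (x-mu2)^2 / 2 s2^2
    a = 1.0 / (2 * s2 * s2) - 1.0 / (2 * s1 * s1)
    b = mu1 / (s1 * s1) - mu2 / (s2 * s2)
    c = (
        mu2 * mu2 / (2 * s2 * s2)
        - mu1 * mu1 / (2 * s1 * s1)
        + math.log(p1 / p2)
        + math.log(s2 / s1)
    )
    disc = b * b - 4 * a * c
    roots = []
    if disc >= 0:
        sq = math.sqrt(disc)
        roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [r for r in roots if mu1 < r < mu2]
    if inside:
        return float(inside[0])
    warnings.warn(
        "no density intersection between the class means; falling back to the "
        "root minimising the weighted misclassification mass",
        RuntimeWarning,
    )
    if not roots:
        return (mu1 + mu2) / 2
    # Pick the real root whose decision rule misclassifies least under the
    # two fitted Gaussians.
    from scipy.stats import norm

    def risk(t: float) -> float:
        return p1 * norm.sf(t, mu1, s1) + p2 * norm.cdf(t, mu2, s2)

    return float(min(roots, key=risk))


def classify(error: ErrorSample, threshold: float) -> str:
    """Drone iff mse > threshold; ties go to worker."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return "drone" if error.mse > threshold else "worker"


def compute_thresholds(
    train_errors: list[ErrorSample],
    worker_calibration: list[ErrorSample],
    drone_calibration: list[ErrorSample],
    priors: tuple[float, float] | None = None,
) -> ThresholdSet:
    """Assemble T1-T3 from training errors and T* from calibration errors.

    ``priors`` defaults to the empirical class proportions of the
    calibration split.
    """
    if priors is None:
        n1, n2 = len(worker_calibration), len(drone_calibration)
        priors = (n1 / (n1 + n2), n2 / (n1 + n2))
    class1 = fit_gaussian(worker_calibration, prior=priors[0])
    class2 = fit_gaussian(drone_calibration, prior=priors[1])
    return ThresholdSet(
        t1=ksigma_threshold(train_errors, 1),
        t2=ksigma_threshold(train_errors, 2),
        t3=ksigma_threshold(train_errors, 3),
        t_star=ml_threshold(class1, class2),
        class1_model=class1,
        class2_model=class2,
    )
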
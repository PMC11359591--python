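"""One-class autoencoder over feature vectors, trained on worker bees only.

The network is a fully connected bottleneck: the encoder steps from the
input dimension down to an 8-neuron code through 1-4 hidden layers whose
sizes interpolate geometrically, and the decoder mirrors the encoder with
one layer fewer, ending in a sigmoid output of the input dimension. All
hidden layers (including the code) use ReLU. Training minimises the mean
squared reconstruction error with Adam on min-max normalised features.

Because the network only ever sees worker-bee features, drone-bee features
reconstruct poorly; the per-segment reconstruction MSE is the
one-dimensional statistic handed to the thresholding stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, DivergenceError
from .features import FeatureVector, feature_matrix


@dataclass(frozen=True)
class AutoencoderConfig:
    input_dim: int
    n_encoder_hidden: int = 2
    code_dim: int = 8
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_encoder_hidden not in (1, 2, 3, 4):
            raise ConfigError("n_encoder_hidden must be in {1, 2, 3, 4}")
        if not 0 < self.code_dim < self.input_dim:
            raise ConfigError("require 0 < code_dim < input_dim")
        if not 0 <= self.validation_fraction < 1:
            raise ConfigError("validation_fraction must be in [0, 1)")


@dataclass(frozen=True)
class ErrorSample:
    """Per-segment reconstruction MSE with its class label."""

    mse: float
    label: str = "unknown"
    source_id: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.mse) or self.mse < 0:
            raise ValueError("mse must be finite and nonnegative")


def encoder_layer_sizes(input_dim: int, n_hidden: int, code_dim: int) -> list[int]:
    """Hidden sizes interpolating geometrically from input_dim to code_dim.

    Size i of n_hidden interior layers is
    round(input_dim * (code_dim/input_dim)^(i/(n_hidden+1))); the resulting
    chain must be strictly decreasing.
    """
    ratio = code_dim / input_dim
    sizes = [input_dim]
    for i in range(1, n_hidden + 1):
        sizes.append(round(input_dim * ratio ** (i / (n_hidden + 1))))
    sizes.append(code_dim)
    if any(b >= a for a, b in zip(sizes, sizes[1:])):
        raise ConfigError(f"layer sizes not strictly decreasing: {sizes}")
    return sizes


def full_layer_sizes(config: AutoencoderConfig) -> list[int]:
    """Complete chain input -> ... -> code -> ... -> output.

    The decoder mirrors the encoder's hidden layers minus the widest one,
    so it has exactly n_encoder_hidden - 1 hidden layers.
    """
    enc = encoder_layer_sizes(config.input_dim, config.n_encoder_hidden, config.code_dim)
    decoder_hidden = enc[1:-1][::-1][:-1]  # mirror, drop the widest
    return enc + decoder_hidden + [config.input_dim]


class MinMaxNormalizer:
    """Per-dimension min-max map onto [0, 1], fitted on training features.

    Constant dimensions map to 0.5; values outside the training range are
    clipped, which the sigmoid output layer requires anyway.
    """

    def __init__(self) -> None:
        self.feature_min: np.ndarray | None = None
        self.feature_max: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "MinMaxNormalizer":
        x = np.asarray(x, dtype=np.float64)
        self.feature_min = x.min(axis=0)
        self.feature_max = x.max(axis=0)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.feature_min is None:
            raise RuntimeError("normalizer not fitted")
        span = self.feature_max - self.feature_min
        constant = span == 0
        safe_span = np.where(constant, 1.0, span)
        out = (np.asarray(x, dtype=np.float64) - self.feature_min) / safe_span
        out = np.where(constant, 0.5, out)
        return np.clip(out, 0.0, 1.0)


class Autoencoder:
    """Feed-forward autoencoder with seeded initialisation and training."""

    def __init__(self, config: AutoencoderConfig):
        self.config = config
        self.layer_sizes = full_layer_sizes(config)
        self.normalizer = MinMaxNormalizer()
        self.training_loss_: list[float] = []
        rng = np.random.default_rng(config.seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.layer_sizes, self.layer_sizes[1:]):
            # He initialisation suits the ReLU stack; the final sigmoid layer
            # tolerates it at these widths.
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._rng = rng

    # -- forward ---------------------------------------------------------

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        """Activations per layer; last entry is the sigmoid output in (0,1)."""
        activations = [x]
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            if i == last:
                h = 1.0 / (1.0 + np.exp(-z))
            else:
                h = np.maximum(z, 0.0)
            activations.append(h)
        return activations

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[-1]

    # -- training --------------------------------------------------------

    def train(self, worker_features: list[FeatureVector]) -> "Autoencoder":
        """Fit on worker-class features by mini-batch Adam on the MSE loss."""
        bad = [f.label for f in worker_features if f.label == "drone"]
        if bad:
            raise ValueError("training features must be worker-class only")
        x = feature_matrix(worker_features)
        if x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"feature dim {x.shape[1]} != configured input_dim {self.config.input_dim}"
            )
        self.normalizer.fit(x)
        xn = self.normalizer.transform(x)

        # Optional held-out worker fraction, monitored per epoch to report
        # generalization MSE; thresholds are computed on training errors by
        # the caller, so this split never leaks into them.
        n_val = int(self.config.validation_fraction * xn.shape[0])
        self.validation_loss_: list[float] = []
        x_val = None
        if n_val >= 1 and xn.shape[0] - n_val >= 2:
            val_idx = self._rng.permutation(xn.shape[0])[:n_val]
            mask = np.ones(xn.shape[0], dtype=bool)
            mask[val_idx] = False
            x_val, xn = xn[~mask], xn[mask]

        lr = self.config.learning_rate
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        m_w = [np.zeros_like(w) for w in self.weights]
        v_w = [np.zeros_like(w) for w in self.weights]
        m_b = [np.zeros_like(b) for b in self.biases]
        v_b = [np.zeros_like(b) for b in self.biases]
        step = 0
        n = xn.shape[0]
        batch = min(self.config.batch_size, n)
        self.training_loss_ = []
        for epoch in range(self.config.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                xb = xn[order[start : start + batch]]
                acts = self.forward(xb)
                out = acts[-1]
                diff = out - xb
                loss = float(np.mean(diff**2))
                epoch_loss += loss * xb.shape[0]
                if not np.isfinite(loss):
                    raise DivergenceError(f"non-finite loss at epoch {epoch}")
                # Backprop: d(mean (out-x)^2)/dz through sigmoid, then ReLU.
                grad = 2.0 * diff / diff.size * out * (1.0 - out)
                step += 1
                for i in range(len(self.weights) - 1, -1, -1):
                    gw = acts[i].T @ grad
                    gb = grad.sum(axis=0)
                    if i > 0:
                        grad = (grad @ self.weights[i].T) * (acts[i] > 0)
                    m_w[i] = beta1 * m_w[i] + (1 - beta1) * gw
                    v_w[i] = beta2 * v_w[i] + (1 - beta2) * gw**2
                    m_b[i] = beta1 * m_b[i] + (1 - beta1) * gb
                    v_b[i] = beta2 * v_b[i] + (1 - beta2) * gb**2
                    mw_hat = m_w[i] / (1 - beta1**step)
                    vw_hat = v_w[i] / (1 - beta2**step)
                    mb_hat = m_b[i] / (1 - beta1**step)
                    vb_hat = v_b[i] / (1 - beta2**step)
                    self.weights[i] -= lr * mw_hat / (np.sqrt(vw_hat) + eps)
                    self.biases[i] -= lr * mb_hat / (np.sqrt(vb_hat) + eps)
            self.training_loss_.append(epoch_loss / n)
            if x_val is not None:
                out_val = self.reconstruct(x_val)
                self.validation_loss_.append(float(np.mean((out_val - x_val) ** 2)))
        return self

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Persist weights, normalizer and config to a single .npz archive."""
        import json

        from dataclasses import asdict

        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        if self.normalizer.feature_min is not None:
            arrays["feature_min"] = self.normalizer.feature_min
            arrays["feature_max"] = self.normalizer.feature_max
        np.savez(
            path,
            config=json.dumps(asdict(self.config)),
            n_layers=len(self.weights),
            training_loss=np.array(self.training_loss_),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "Autoencoder":
        import json

        with np.load(path, allow_pickle=False) as data:
            config = AutoencoderConfig(**json.loads(str(data["config"])))
            net = cls(config)
            n = int(data["n_layers"])
            net.weights = [data[f"w{i}"] for i in range(n)]
            net.biases = [data[f"b{i}"] for i in range(n)]
            if "feature_min" in data:
                net.normalizer.feature_min = data["feature_min"]
                net.normalizer.feature_max = data["feature_max"]
            net.training_loss_ = [float(v) for v in data["training_loss"]]
        return net

    # -- inference -------------------------------------------------------

    def reconstruction_error(self, feature: FeatureVector) -> ErrorSample:
        """Mean squared reconstruction error of one normalised feature."""
        if feature.dim != self.config.input_dim:
            raise ValueError(
                f"feature dim {feature.dim} != configured input_dim {self.config.input_dim}"
            )
        xn = self.normalizer.transform(feature.values[None, :])
        out = self.reconstruct(xn)
        mse = float(np.mean((out - xn) ** 2))
        return ErrorSample(mse=mse, label=feature.label, source_id=feature.source_id)

    def reconstruction_errors(self, features: list[FeatureVector]) -> list[ErrorSample]:
        if not features:
            return []
        x = feature_matrix(features)
        if x.shape[1] != self.config.input_dim:
            raise ValueError("feature dimension mismatch")
        xn = self.normalizer.transform(x)
        out = self.reconstruct(xn)
        mses = np.mean((out - xn) ** 2, axis=1)
        return [
            ErrorSample(mse=float(m), label=f.label, source_id=f.source_id)
            for m, f in zip(mses, features)
        ]
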
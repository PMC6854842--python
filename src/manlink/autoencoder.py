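"""Dense autoencoder unifying attribute dimensions across node types.

Raw attribute vectors differ in length per molecule type (64 for sequence
k-mers, 1024 for drug fingerprints, n_diseases for disease similarity
rows). One autoencoder is trained per type, all sharing the same latent
dimension (default 64), so every node's encoded attribute lives in a
comparable learned space. The network is input -> hidden -> latent ->
hidden -> input with rectified-linear activations f(t) = max(0, W t + b)
on the hidden and latent layers, trained by seeded mini-batch gradient
descent on the summed squared reconstruction error
L = sum_i ||x_hat_i - x_i||^2. Inputs are centered on the training mean
before entering the network (attribute vectors are non-negative and far
from zero mean; training on raw values drives correlated gradients that
kill rectified latent units), and the reconstruction layer is linear so
that clamped output units keep receiving gradient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["AutoencoderConfig", "TrainedEncoder", "train_autoencoder", "encode", "reconstruct"]


@dataclass(frozen=True)
class AutoencoderConfig:
    input_dim: int
    latent_dim: int = 64
    hidden_dims: tuple[int, ...] = (256,)
    epochs: int = 300
    learning_rate: float = 1e-2
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim > self.input_dim:
            raise ValueError("latent_dim must not exceed input_dim")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @property
    def layer_dims(self) -> list[int]:
        # symmetric encoder/decoder stack
        enc = [self.input_dim, *self.hidden_dims, self.latent_dim]
        dec = [*reversed(self.hidden_dims), self.input_dim]
        return enc + dec


@dataclass
class TrainedEncoder:
    config: AutoencoderConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    center: np.ndarray = field(default_factory=lambda: np.zeros(0))
    loss_trace: list[float] = field(default_factory=list)

    @property
    def n_encoder_layers(self) -> int:
        return len(self.config.hidden_dims) + 1

    def save_loss_trace(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "config": {
                        "input_dim": self.config.input_dim,
                        "latent_dim": self.config.latent_dim,
                        "hidden_dims": list(self.config.hidden_dims),
                        "epochs": self.config.epochs,
                        "learning_rate": self.config.learning_rate,
                        "batch_size": self.config.batch_size,
                        "seed": self.config.seed,
                    },
                    "loss_trace": self.loss_trace,
                },
                fh,
                indent=2,
            )
            fh.write("\n")


def _forward(
    X: np.ndarray,
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    linear_output: bool = True,
) -> list[np.ndarray]:
    """Activations per layer: ReLU on hidden and latent layers, linear on
    the final reconstruction layer (a rectified output unit whose
    pre-activation goes negative would receive no gradient and stay dead,
    so real-valued reconstruction uses an identity output)."""
    acts = [X]
    last = len(weights) - 1
    for i, (W, b) in enumerate(zip(weights, biases)):
        z = acts[-1] @ W + b
        acts.append(z if (linear_output and i == last) else np.maximum(0.0, z))
    return acts


def _loss(X: np.ndarray, X_hat: np.ndarray) -> float:
    return float(np.sum((X_hat - X) ** 2))


def train_autoencoder(X: np.ndarray, config: AutoencoderConfig) -> TrainedEncoder:
    """Fit the autoencoder by mini-batch gradient descent.

    Deterministic for a fixed seed (initialization and batch shuffling both
    draw from one seeded generator). Raises on non-finite inputs or on a
    diverging loss.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("X must be a non-empty 2-D array")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains NaN or Inf")
    if X.shape[1] != config.input_dim:
        raise ValueError(f"X has {X.shape[1]} columns, config expects {config.input_dim}")

    rng = np.random.default_rng(config.seed)
    center = X.mean(axis=0)
    X = X - center
    dims = config.layer_dims
    # He initialization, suited to rectifier activations
    weights = [
        rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
        for i in range(len(dims) - 1)
    ]
    biases = [np.full(dims[i + 1], 0.01) for i in range(len(dims) - 1)]

    n = X.shape[0]
    batch = min(config.batch_size, n)
    # trace[0] is the pre-training loss; one entry per epoch follows
    trace: list[float] = [_loss(X, _forward(X, weights, biases)[-1])]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            xb = X[order[start : start + batch]]
            acts = _forward(xb, weights, biases)
            # backprop of L = sum ||x_hat - x||^2 through the ReLU stack;
            # gradients averaged over the batch for step-size stability
            delta = 2.0 * (acts[-1] - xb) / xb.shape[0]  # linear output layer
            for layer in range(len(weights) - 1, -1, -1):
                gW = acts[layer].T @ delta
                gb = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ weights[layer].T) * (acts[layer] > 0)
                weights[layer] -= config.learning_rate * gW
                biases[layer] -= config.learning_rate * gb
        epoch_loss = _loss(X, _forward(X, weights, biases)[-1])
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                "autoencoder loss diverged; try a smaller learning_rate"
            )
        trace.append(epoch_loss)

    return TrainedEncoder(
        config=config, weights=weights, biases=biases, center=center,
        loss_trace=trace,
    )


def encode(encoder: TrainedEncoder, X: np.ndarray) -> np.ndarray:
    """Latent representations (n x latent_dim, entries >= 0)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != encoder.config.input_dim:
        raise ValueError(
            f"input has {X.shape[1]} columns, encoder expects {encoder.config.input_dim}"
        )
    k = encoder.n_encoder_layers
    acts = _forward(
        X - encoder.center, encoder.weights[:k], encoder.biases[:k],
        linear_output=False,
    )
    return acts[-1]


def reconstruct(encoder: TrainedEncoder, X: np.ndarray) -> np.ndarray:
    """Full encode-decode pass on the original (uncentered) scale."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    out = _forward(X - encoder.center, encoder.weights, encoder.biases)[-1]
    return out + encoder.center
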
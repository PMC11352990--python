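"""Continuous Dictionary of Nodes: per-subject linear autoencoder.

The subject's Fisher-z network (n x n) is split column-by-column into n
samples of length n, and a three-layer linear autoencoder

    h = sigma(We x + be),    x_hat = sigma(Wd h + bd)

is trained on those samples by full-batch gradient descent on the mean
squared reconstruction error.  The model is deliberately linear (sigma is
the identity by default; a hook is kept for experimentation) and shallow:
one hidden layer of m units (default 40, below the node count, so the
encoder compresses).

The point of the model is not reconstruction but its weights: the encoder
weight matrix We (m x n) is read out, transposed, as an n x m matrix of
per-node latent features — row i holds the latent feature vector of node i.
The decoder weights Wd (n x m) give an alternative, typically weaker,
feature set and are exposed for ablation.

One model is trained per subject; there is no train/test split and no
weight sharing across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .connectome_io import ConnectivityMatrix
from .exceptions import DivergenceError, ValidationError


@dataclass
class CdonConfig:
    """Training configuration for the per-subject autoencoder.

    ``activation`` accepts ``None`` (identity, the default and the model's
    definition) or a pair of callables ``(f, f_prime)`` applied element-wise.
    """

    hidden_units: int = 40
    epochs: int = 2000
    learning_rate: float = 1.0
    seed: int = 0
    init_scale: float = 1.0
    activation: tuple[Callable, Callable] | None = None

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValidationError("hidden_units must be >= 1")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.init_scale <= 0:
            raise ValidationError("init_scale must be > 0")


@dataclass
class CdonWeights:
    """Trained parameters plus the loss trajectory."""

    We_raw: np.ndarray  # (m, n) encoder weight
    Wd_raw: np.ndarray  # (n, m) decoder weight
    be: np.ndarray  # (m,)
    bd: np.ndarray  # (n,)
    final_loss: float
    loss_history: list[float]

    def __post_init__(self) -> None:
        m, n = self.We_raw.shape
        if self.Wd_raw.shape != (n, m) or self.be.shape != (m,) or self.bd.shape != (n,):
            raise ValidationError("inconsistent weight shapes")
        if not self.loss_history:
            raise ValidationError("loss_history must be non-empty")


@dataclass
class LatentFeatures:
    """n x m node latent features; row i belongs to node i."""

    subject_id: str
    F: np.ndarray
    source: str  # "encoder" | "decoder"

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2:
            raise ValidationError("latent features must be a 2-D matrix")
        if not np.isfinite(self.F).all():
            raise ValidationError("latent features contain non-finite entries")
        if self.source not in ("encoder", "decoder"):
            raise ValidationError(f"unknown latent source {self.source!r}")

    @property
    def n_nodes(self) -> int:
        return self.F.shape[0]


def split_columns(cm: ConnectivityMatrix) -> list[np.ndarray]:
    """Split the n x n network into its n column vectors (the training samples)."""
    return [cm.values[:, j].copy() for j in range(cm.n_nodes)]


def initial_weights(n: int, m: int, cfg: CdonConfig) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform(-s, s)/sqrt(n) weight initialisation, zero biases elsewhere."""
    rng = np.random.default_rng(cfg.seed)
    s = cfg.init_scale / np.sqrt(n)
    We0 = rng.uniform(-s, s, size=(m, n))
    Wd0 = rng.uniform(-s, s, size=(n, m))
    return We0, Wd0


def mse_loss_and_grads(
    X: np.ndarray,
    We: np.ndarray,
    Wd: np.ndarray,
    be: np.ndarray,
    bd: np.ndarray,
    activation: tuple[Callable, Callable] | None = None,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Loss (mean over all matrix entries) and analytic gradients.

    ``X`` is n x N with one sample per column.  Exposed so the gradients can
    be checked against central differences.
    """
    n, N = X.shape
    Ae = We @ X + be[:, None]
    H = Ae if activation is None else activation[0](Ae)
    Ad = Wd @ H + bd[:, None]
    Xhat = Ad if activation is None else activation[0](Ad)
    R = Xhat - X
    loss = float(np.mean(R * R))
    G = (2.0 / (n * N)) * R
    if activation is not None:
        G = G * activation[1](Ad)
    dWd = G @ H.T
    dbd = G.sum(axis=1)
    dH = Wd.T @ G
    if activation is not None:
        dH = dH * activation[1](Ae)
    dWe = dH @ X.T
    dbe = dH.sum(axis=1)
    return loss, dWe, dWd, dbe, dbd


def train_cdon(
    samples: Sequence[np.ndarray],
    cfg: CdonConfig,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> CdonWeights:
    """Full-batch gradient descent on the column samples.

    ``init`` optionally overrides the seeded (We0, Wd0) initialisation,
    which is needed for equivariance experiments.  Deterministic given the
    seed: two runs with identical inputs produce bit-identical histories.
    """
    samples = [np.asarray(s, dtype=float).ravel() for s in samples]
    if not samples:
        raise ValidationError("no training samples")
    n = samples[0].size
    if any(s.size != n for s in samples):
        raise ValidationError("all samples must have the same length")
    X = np.stack(samples, axis=1)  # (n, N)
    m = cfg.hidden_units

    if init is None:
        We, Wd = initial_weights(n, m, cfg)
    else:
        We, Wd = (np.array(init[0], dtype=float), np.array(init[1], dtype=float))
        if We.shape != (m, n) or Wd.shape != (n, m):
            raise ValidationError("init weight shapes do not match config")
    be = np.zeros(m)
    bd = np.zeros(n)

    lr = cfg.learning_rate
    history: list[float] = []
    for epoch in range(cfg.epochs):
        loss, dWe, dWd, dbe, dbd = mse_loss_and_grads(X, We, Wd, be, bd, cfg.activation)
        if not np.isfinite(loss):
            raise DivergenceError(
                f"non-finite loss at epoch {epoch}; reduce learning_rate (lr={lr})"
            )
        We -= lr * dWe
        Wd -= lr * dWd
        be -= lr * dbe
        bd -= lr * dbd
        history.append(loss)

    final_loss, *_ = mse_loss_and_grads(X, We, Wd, be, bd, cfg.activation)
    if not np.isfinite(final_loss):
        raise DivergenceError(f"non-finite final loss; reduce learning_rate (lr={lr})")
    history.append(final_loss)
    return CdonWeights(We, Wd, be, bd, final_loss, history)


def extract_latent(w: CdonWeights, source: str = "encoder", subject_id: str = "") -> LatentFeatures:
    """Read node latent features out of the trained weights.

    encoder: F = We^T (n x m, row per node); decoder: F = Wd (already n x m).
    """
    if source == "encoder":
        F = w.We_raw.T.copy()
    elif source == "decoder":
        F = w.Wd_raw.copy()
    else:
        raise ValidationError(f"unknown latent source {source!r}")
    return LatentFeatures(subject_id, F, source)
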
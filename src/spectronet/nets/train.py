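"""Adam training of frame classifiers with weighted cross-entropy.

Defaults follow the training recipe: batch 32, up to 600 epochs, learning
rate 0.001, beta1 = beta2 = 0.9 (the unconventional beta2 is honoured as
printed; set ``beta2=0.999`` for the conventional value), dropout active
during training only, and early stopping on the plateau of the epoch-mean
training loss (no validation split exists under leave-pair-out CV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import DTYPE
from .models import Network, softmax

__all__ = ["TrainConfig", "train", "predict_frames", "cross_entropy",
           "standardize", "Standardizer"]


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.9
    eps: float = 1e-8
    batch_size: int = 32
    max_epochs: int = 600
    patience: int = 25
    min_delta: float = 1e-4
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise TrainingError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise TrainingError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise TrainingError("max_epochs must be >= 1")


@dataclass
class Standardizer:
    """Scalar z-scoring fitted on training-fold frames only (no leakage)."""

    mean: float
    sd: float

    @classmethod
    def fit(cls, frames: np.ndarray) -> "Standardizer":
        sd = float(frames.std())
        return cls(mean=float(frames.mean()), sd=sd if sd > 0 else 1.0)

    def apply(self, frames: np.ndarray) -> np.ndarray:
        return ((frames - self.mean) / self.sd).astype(DTYPE)


def standardize(train_frames: np.ndarray, *others: np.ndarray):
    """Z-score training frames; apply the same transform to held-out sets."""
    scaler = Standardizer.fit(train_frames)
    out = [scaler.apply(train_frames)] + [scaler.apply(o) for o in others]
    return (*out, scaler)


def cross_entropy(logits: np.ndarray, y: np.ndarray,
                  weights: np.ndarray | None = None
                  ) -> tuple[float, np.ndarray]:
    """Weighted mean cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    if weights is None:
        weights = np.ones(n, dtype=DTYPE)
    probs = softmax(logits)
    eps = 1e-12
    w_sum = weights.sum()
    loss = float(-(weights * np.log(probs[np.arange(n), y] + eps)).sum() / w_sum)
    grad = probs.astype(DTYPE)
    grad[np.arange(n), y] -= 1.0
    grad *= (weights / w_sum)[:, None]
    return loss, grad


class Adam:
    def __init__(self, params: list[np.ndarray], config: TrainConfig):
        self.params = params
        self.cfg = config
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1 ** self.t
        bc2 = 1.0 - c.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= c.beta1
            m += (1.0 - c.beta1) * g
            v *= c.beta2
            v += (1.0 - c.beta2) * g * g
            p -= c.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + c.eps)


def train(model: Network, frames: np.ndarray, labels: np.ndarray,
          sample_weights: np.ndarray | None = None,
          config: TrainConfig = TrainConfig()) -> Network:
    """Minimize weighted cross-entropy over mini-batches; returns the model
    with ``history`` holding the per-epoch mean training loss."""
    config.validate()
    y = np.asarray(labels, dtype=np.int64)
    if np.unique(y).size < 2:
        raise TrainingError("training labels must contain every class")
    x = np.asarray(frames, dtype=DTYPE)
    if sample_weights is None:
        w = np.ones(len(x), dtype=DTYPE)
    else:
        w = np.asarray(sample_weights, dtype=DTYPE)
        if w.shape != (len(x),):
            raise TrainingError("sample_weights length must match frame count")
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise TrainingError("sample_weights must be positive and finite")

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.params(), config)
    model.history = []
    best = np.inf
    stall = 0
    n = len(x)
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        total, wtot = 0.0, 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(x[idx], train=True)
            loss, dlogits = cross_entropy(logits, y[idx], w[idx])
            model.backward(dlogits)
            optimizer.step(model.grads())
            bw = float(w[idx].sum())
            total += loss * bw
            wtot += bw
        epoch_loss = total / wtot
        model.history.append(epoch_loss)
        if epoch_loss < best - config.min_delta:
            best = epoch_loss
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    return model


def predict_frames(model: Network, frames: np.ndarray) -> np.ndarray:
    """Per-frame two-class probability vectors (rows sum to 1)."""
    return model.predict_proba(np.asarray(frames, dtype=DTYPE))
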
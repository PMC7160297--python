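"""The three classifier architectures.

The CNN hyperparameters that the printed parameter total does not pin down
(kernel sizes, filter counts, padding, pooling edges) were frozen by an
exhaustive search over kernel sizes {3,5} (per axis), filter counts 4..64,
same/valid padding and floor/ceil 2x2 pooling, constrained to two
conv/pool blocks followed by 128- and 64-unit dense layers and a 2-class
head, keeping a configuration whose trainable-parameter total is exactly
75106 (several exist; the frozen one below is the cheapest to evaluate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (DTYPE, Conv2D, Dense, Dropout, Flatten, LSTM, LastStep,
                     Layer, MaxPool2x2, ReLU, TimeMajor)

__all__ = ["CnnConfig", "RnnConfig", "SnnConfig", "Network",
           "build_cnn", "build_rnn", "build_snn", "build_model",
           "save_model", "load_model", "CNN_PARAM_TOTAL"]

CNN_PARAM_TOTAL = 75106

INPUT_SHAPE = (22, 20, 7)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class CnnConfig:
    input_shape: tuple[int, int, int] = INPUT_SHAPE
    # frozen conv blocks: (kh, kw, filters, padding)
    conv1: tuple[int, int, int, str] = (3, 5, 5, "same")
    conv2: tuple[int, int, int, str] = (3, 3, 17, "same")
    dense_units: tuple[int, int] = (128, 64)
    n_classes: int = 2
    init_sd: float = 0.1
    conv_dropout: float = 0.2
    dense_dropout: float = 0.4
    target_param_total: int | None = CNN_PARAM_TOTAL

    def with_channels(self, n_channels: int) -> "CnnConfig":
        """Adapt to a channel subset; the parameter-count lock only applies
        to the default 7-channel stack."""
        shape = (self.input_shape[0], self.input_shape[1], n_channels)
        target = self.target_param_total if n_channels == INPUT_SHAPE[2] else None
        return CnnConfig(input_shape=shape, conv1=self.conv1, conv2=self.conv2,
                         dense_units=self.dense_units, n_classes=self.n_classes,
                         init_sd=self.init_sd, conv_dropout=self.conv_dropout,
                         dense_dropout=self.dense_dropout,
                         target_param_total=target)


@dataclass(frozen=True)
class RnnConfig:
    input_shape: tuple[int, int, int] = INPUT_SHAPE
    n_layers: int = 3
    hidden_units: int = 32
    dropout: float = 0.2
    n_classes: int = 2
    init_sd: float = 0.1

    def with_channels(self, n_channels: int) -> "RnnConfig":
        shape = (self.input_shape[0], self.input_shape[1], n_channels)
        return RnnConfig(input_shape=shape, n_layers=self.n_layers,
                         hidden_units=self.hidden_units, dropout=self.dropout,
                         n_classes=self.n_classes, init_sd=self.init_sd)


@dataclass(frozen=True)
class SnnConfig:
    input_shape: tuple[int, int, int] = INPUT_SHAPE
    hidden_units: int = 1024
    dropout: float = 0.3
    n_classes: int = 2
    init_sd: float = 0.1

    def with_channels(self, n_channels: int) -> "SnnConfig":
        shape = (self.input_shape[0], self.input_shape[1], n_channels)
        return SnnConfig(input_shape=shape, hidden_units=self.hidden_units,
                         dropout=self.dropout, n_classes=self.n_classes,
                         init_sd=self.init_sd)


class Network:
    """Sequential feed-forward container emitting 2-class logits.

    ``forward`` keeps the caches needed by ``backward``; ``backward`` returns
    the gradient with respect to the input, which activation maximization
    relies on.
    """

    def __init__(self, layers: list[Layer], arch: str, config: object):
        self.layers = layers
        self.arch = arch
        self.config = config
        self.history: list[float] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params()))

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Per-frame class probabilities; deterministic (dropout disabled)."""
        outs = []
        for start in range(0, len(x), batch_size):
            logits = self.forward(x[start:start + batch_size], train=False)
            outs.append(softmax(logits))
        return np.concatenate(outs, axis=0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_cnn(config: CnnConfig = CnnConfig(), seed: int = 0) -> Network:
    """Two conv/ReLU/pool/dropout blocks, dense 128 and 64, 2-logit head."""
    rng = np.random.default_rng(seed)
    h, w, c = config.input_shape
    kh1, kw1, c1, pad1 = config.conv1
    kh2, kw2, c2, pad2 = config.conv2

    def conv_out(n, k, pad):
        return n if pad == "same" else n - k + 1

    def pool_out(n):  # ceil mode
        return (n + 1) // 2

    layers: list[Layer] = [
        Conv2D(kh1, kw1, c, c1, pad1, rng, config.init_sd),
        ReLU(),
        MaxPool2x2(),
        Dropout(config.conv_dropout, rng),
        Conv2D(kh2, kw2, c1, c2, pad2, rng, config.init_sd),
        ReLU(),
        MaxPool2x2(),
        Dropout(config.conv_dropout, rng),
        Flatten(),
    ]
    h1, w1 = pool_out(conv_out(h, kh1, pad1)), pool_out(conv_out(w, kw1, pad1))
    h2, w2 = pool_out(conv_out(h1, kh2, pad2)), pool_out(conv_out(w1, kw2, pad2))
    flat = h2 * w2 * c2
    d1, d2 = config.dense_units
    layers += [
        Dense(flat, d1, rng, config.init_sd), ReLU(),
        Dropout(config.dense_dropout, rng),
        Dense(d1, d2, rng, config.init_sd), ReLU(),
        Dense(d2, config.n_classes, rng, config.init_sd),
    ]
    net = Network(layers, "cnn", config)
    if config.target_param_total is not None \
            and net.param_count() != config.target_param_total:
        raise ConfigurationError(
            f"CNN has {net.param_count()} trainable parameters, expected "
            f"{config.target_param_total}")
    return net


def build_rnn(config: RnnConfig = RnnConfig(), seed: int = 0) -> Network:
    """Three stacked LSTM layers over the time axis, dropout between layers.

    Each (freq, time, channel) stack is presented as a time-major sequence:
    n_times steps of n_freqs x n_channels feature vectors.
    """
    rng = np.random.default_rng(seed)
    n_freqs, n_times, n_ch = config.input_shape
    d_in = n_freqs * n_ch
    layers: list[Layer] = [TimeMajor()]
    d = d_in
    for _ in range(config.n_layers):
        layers.append(LSTM(d, config.hidden_units, rng, config.init_sd))
        layers.append(Dropout(config.dropout, rng))
        d = config.hidden_units
    layers.append(LastStep())
    layers.append(Dense(config.hidden_units, config.n_classes, rng, config.init_sd))
    return Network(layers, "rnn", config)


def build_snn(config: SnnConfig = SnnConfig(), seed: int = 0) -> Network:
    """Flatten -> 1024-unit ReLU layer -> 2-logit head."""
    rng = np.random.default_rng(seed)
    h, w, c = config.input_shape
    layers: list[Layer] = [
        Flatten(),
        Dense(h * w * c, config.hidden_units, rng, config.init_sd),
        ReLU(),
        Dropout(config.dropout, rng),
        Dense(config.hidden_units, config.n_classes, rng, config.init_sd),
    ]
    return Network(layers, "snn", config)


def save_model(model: Network, path) -> None:
    """Checkpoint: architecture tag, channel count and parameter arrays."""
    n_channels = model.config.input_shape[2]  # type: ignore[attr-defined]
    arrays = {f"p{i}": p for i, p in enumerate(model.params())}
    np.savez(path, arch=model.arch, n_channels=n_channels, **arrays)


def load_model(path) -> Network:
    with np.load(path, allow_pickle=False) as data:
        arch = str(data["arch"])
        model = build_model(arch, n_channels=int(data["n_channels"]))
        for i, p in enumerate(model.params()):
            p[...] = data[f"p{i}"]
    return model


def build_model(arch: str, n_channels: int = 7, seed: int = 0) -> Network:
    """Factory by architecture tag, adapted to the channel count."""
    if arch == "cnn":
        return build_cnn(CnnConfig().with_channels(n_channels), seed=seed)
    if arch == "rnn":
        return build_rnn(RnnConfig().with_channels(n_channels), seed=seed)
    if arch == "snn":
        return build_snn(SnnConfig().with_channels(n_channels), seed=seed)
    raise ConfigurationError(f"unknown architecture {arch!r}")
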
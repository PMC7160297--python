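"""Minimal NumPy layers with forward/backward passes.

Only what the three architectures need: 2-D convolution (stride 1),
2x2 max-pooling with ceil-mode edges, dense layers, ReLU, inverted dropout
and stacked LSTMs.  All layers propagate gradients back to their input so
the input gradient is available for activation maximization.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Conv2D", "MaxPool2x2", "ReLU", "Dropout", "Flatten",
           "Dense", "LSTM", "LastStep"]

DTYPE = np.float32


class Layer:
    """Base layer; stateless layers only override forward/backward."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 convolution over (N, H, W, C) input.

    padding="same" keeps the spatial size; "valid" shrinks by kernel-1.
    """

    def __init__(self, kh: int, kw: int, c_in: int, c_out: int,
                 padding: str, rng: np.random.Generator, init_sd: float = 0.1):
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        self.kh, self.kw, self.padding = kh, kw, padding
        self.w = rng.normal(0.0, init_sd, size=(kh, kw, c_in, c_out)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def _pads(self):
        if self.padding == "same":
            ph, pw = self.kh - 1, self.kw - 1
            return (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)
        return (0, 0), (0, 0)

    def forward(self, x, train=False):
        (pt, pb), (pl, pr) = self._pads()
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        n, hp, wp, c = xp.shape
        oh, ow = hp - self.kh + 1, wp - self.kw + 1
        # accumulate one GEMM per kernel offset; faster than im2col for the
        # small channel counts used here
        out = np.broadcast_to(self.b, (n, oh, ow, self.b.size)).copy()
        for a in range(self.kh):
            for b_ in range(self.kw):
                patch = xp[:, a:a + oh, b_:b_ + ow, :].reshape(-1, c)
                out += (patch @ self.w[a, b_]).reshape(n, oh, ow, -1)
        self._xp = xp
        self._oshape = (n, oh, ow)
        return out

    def backward(self, dout):
        xp = self._xp
        n, oh, ow = self._oshape
        c_in = xp.shape[-1]
        dflat = dout.reshape(-1, dout.shape[-1])
        dxp = np.zeros_like(xp)
        for a in range(self.kh):
            for b_ in range(self.kw):
                patch = xp[:, a:a + oh, b_:b_ + ow, :].reshape(-1, c_in)
                self.dw[a, b_] = patch.T @ dflat
                dxp[:, a:a + oh, b_:b_ + ow, :] += \
                    (dflat @ self.w[a, b_].T).reshape(n, oh, ow, c_in)
        self.db[...] = dflat.sum(axis=0)
        (pt, pb), (pl, pr) = self._pads()
        return dxp[:, pt:xp.shape[1] - pb or None, pl:xp.shape[2] - pr or None, :]


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2, ceil mode (odd edges padded with -inf)."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        h2, w2 = (h + 1) // 2, (w + 1) // 2
        xp = np.full((n, 2 * h2, 2 * w2, c), -np.inf, dtype=x.dtype)
        xp[:, :h, :w, :] = x
        windows = xp.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4) \
            .reshape(n, h2, w2, c, 4)
        self._argmax = windows.argmax(axis=-1)
        self._ishape = (n, h, w, c)
        return windows.max(axis=-1)

    def backward(self, dout):
        n, h, w, c = self._ishape
        h2, w2 = dout.shape[1], dout.shape[2]
        dxp = np.zeros((n, h2, w2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dxp, self._argmax[..., None], dout[..., None], axis=-1)
        dxp = dxp.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3) \
            .reshape(n, 2 * h2, 2 * w2, c)
        return dxp[:, :h, :w, :]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference and when rate == 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 init_sd: float = 0.1):
        self.w = rng.normal(0.0, init_sd, size=(d_in, d_out)).astype(DTYPE)
        self.b = np.zeros(d_out, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.w.T


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    """Single LSTM layer over (N, T, D) input, returning the full (N, T, H)
    hidden sequence.  Gate order in the packed weight matrix: i, f, g, o."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 init_sd: float = 0.1):
        self.h = hidden
        self.w = rng.normal(0.0, init_sd, size=(d_in + hidden, 4 * hidden)).astype(DTYPE)
        self.b = np.zeros(4 * hidden, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, train=False):
        n, t_steps, d = x.shape
        h = self.h
        hs = np.zeros((n, t_steps, h), dtype=DTYPE)
        self._cache = []
        h_prev = np.zeros((n, h), dtype=DTYPE)
        c_prev = np.zeros((n, h), dtype=DTYPE)
        for t in range(t_steps):
            z = np.concatenate([x[:, t, :], h_prev], axis=1)
            gates = z @ self.w + self.b
            i = _sigmoid(gates[:, :h])
            f = _sigmoid(gates[:, h:2 * h])
            g = np.tanh(gates[:, 2 * h:3 * h])
            o = _sigmoid(gates[:, 3 * h:])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_new = o * tc
            hs[:, t, :] = h_new
            self._cache.append((z, i, f, g, o, c_prev, tc))
            h_prev, c_prev = h_new, c
        self._x_shape = x.shape
        return hs

    def backward(self, dout):
        n, t_steps, _ = self._x_shape
        h = self.h
        dx = np.zeros(self._x_shape, dtype=DTYPE)
        self.dw[...] = 0.0
        self.db[...] = 0.0
        dh_next = np.zeros((n, h), dtype=DTYPE)
        dc_next = np.zeros((n, h), dtype=DTYPE)
        for t in reversed(range(t_steps)):
            z, i, f, g, o, c_prev, tc = self._cache[t]
            dh = dout[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dgates = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ], axis=1)
            self.dw += z.T @ dgates
            self.db += dgates.sum(axis=0)
            dz = dgates @ self.w.T
            dx[:, t, :] = dz[:, :dz.shape[1] - h]
            dh_next = dz[:, dz.shape[1] - h:]
            dc_next = dc * f
        return dx


class TimeMajor(Layer):
    """View a (N, F, T, C) stack as a (N, T, F*C) sequence."""

    def forward(self, x, train=False):
        n, f, t, c = x.shape
        self._shape = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, t, f * c)

    def backward(self, dout):
        n, f, t, c = self._shape
        return dout.reshape(n, t, f, c).transpose(0, 2, 1, 3)


class LastStep(Layer):
    """Select the final time step of a (N, T, H) sequence."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, dout):
        dx = np.zeros(self._shape, dtype=dout.dtype)
        dx[:, -1, :] = dout
        return dx
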
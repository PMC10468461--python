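"""Minimal sequence-model core: layers, manual backprop, Adam.

This package trains two small networks — a Bi-LSTM+CNN lead generator and a
1-D CNN classifier — on fixed-length ECG sequences.  The layers here provide
exactly what those models need (dense, 1-D convolution, max-pooling, ReLU,
uni/bidirectional LSTM) with hand-derived gradients and an Adam optimizer,
all in NumPy.  Everything is deterministic given the seed of the
``numpy.random.Generator`` used at initialization, which makes training
bit-reproducible on a fixed platform.

Array layout is channels-last: sequence tensors are (batch, time, features).
Gradient correctness is enforced by finite-difference checks in the test
suite; float64 is used there, float32 for training speed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Dense",
    "ReLU",
    "Conv1D",
    "MaxPool1D",
    "LSTM",
    "BiLSTM",
    "Flatten",
    "Sequential",
    "Adam",
    "mse_loss",
    "bce_with_logits_loss",
]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base layer: forward caches what backward needs; params/grads by name."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    """Affine map on the last axis; works framewise on (B, T, F) or flat (B, F)."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        self.W = _glorot(rng, (in_features, out_features), dtype)
        self.b = np.zeros(out_features, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        x = self._x
        flat_x = x.reshape(-1, x.shape[-1])
        flat_dy = dy.reshape(-1, dy.shape[-1])
        self.dW = flat_x.T @ flat_dy
        self.db = flat_dy.sum(axis=0)
        return dy @ self.W.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Flatten(Layer):
    """(B, T, C) -> (B, T*C)."""

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Conv1D(Layer):
    """1-D convolution, stride 1, 'same' zero padding (length-preserving)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        self.k = kernel_size
        self.cin = in_channels
        self.cout = out_channels
        self.W = _glorot(rng, (kernel_size * in_channels, out_channels), dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x):
        B, T, C = x.shape
        pl = (self.k - 1) // 2
        pr = self.k - 1 - pl
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        # windows[b, t, i, c] = xp[b, t + i, c]
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        # sliding_window_view puts the window axis last: (B, T, C, k)
        patches = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, T, self.k * C)
        self._patches = patches
        self._pl, self._T = pl, T
        return patches @ self.W + self.b

    def backward(self, dy):
        B, T, _ = dy.shape
        flat_p = self._patches.reshape(-1, self.k * self.cin)
        flat_dy = dy.reshape(-1, self.cout)
        self.dW = flat_p.T @ flat_dy
        self.db = flat_dy.sum(axis=0)
        Wk = self.W.reshape(self.k, self.cin, self.cout)
        dxp = np.zeros((B, T + self.k - 1, self.cin), dtype=dy.dtype)
        for i in range(self.k):
            dxp[:, i : i + T, :] += dy @ Wk[i].T
        return dxp[:, self._pl : self._pl + T, :]


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time; trailing remainder is dropped."""

    def __init__(self, pool: int = 2) -> None:
        self.pool = pool

    def forward(self, x):
        B, T, C = x.shape
        T2 = T // self.pool
        self._in_shape = x.shape
        xr = x[:, : T2 * self.pool, :].reshape(B, T2, self.pool, C)
        self._arg = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, dy):
        B, T2, C = dy.shape
        dxr = np.zeros((B, T2, self.pool, C), dtype=dy.dtype)
        b_idx, t_idx, c_idx = np.ogrid[:B, :T2, :C]
        dxr[b_idx, t_idx, self._arg, c_idx] = dy
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : T2 * self.pool, :] = dxr.reshape(B, T2 * self.pool, C)
        return dx


class LSTM(Layer):
    """Single-direction LSTM returning the full hidden sequence.

    Gate order i, f, g, o; forget-gate bias initialized to 1.  ``reverse=True``
    processes the sequence back-to-front with outputs re-aligned to input
    positions (the building block of the bidirectional wrapper).
    """

    def __init__(self, in_features: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False, dtype=np.float32) -> None:
        self.h = hidden
        self.reverse = reverse
        self.Wx = _glorot(rng, (in_features, 4 * hidden), dtype)
        self.Wh = _glorot(rng, (hidden, 4 * hidden), dtype)
        self.b = np.zeros(4 * hidden, dtype=dtype)
        self.b[hidden : 2 * hidden] = 1.0
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def grads(self):
        return {"Wx": self.dWx, "Wh": self.dWh, "b": self.db}

    def forward(self, x):
        if self.reverse:
            x = x[:, ::-1, :]
        B, T, F = x.shape
        H = self.h
        zx = x.reshape(-1, F) @ self.Wx + self.b  # (B*T, 4H), one big matmul
        zx = zx.reshape(B, T, 4 * H)
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        I = np.empty((B, T, H), dtype=x.dtype)
        Fg = np.empty_like(I)
        G = np.empty_like(I)
        O = np.empty_like(I)
        Cs = np.empty_like(I)
        Tc = np.empty_like(I)
        Hprev = np.empty_like(I)
        Cprev = np.empty_like(I)
        for t in range(T):
            Hprev[:, t] = h
            Cprev[:, t] = c
            z = zx[:, t] + h @ self.Wh
            zi, zf, zg, zo = np.split(z, 4, axis=1)
            i = expit(zi)
            f = expit(zf)
            g = np.tanh(zg)
            o = expit(zo)
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            I[:, t], Fg[:, t], G[:, t], O[:, t] = i, f, g, o
            Cs[:, t], Tc[:, t] = c, tc
        self._cache = (x, I, Fg, G, O, Cs, Tc, Hprev, Cprev)
        hs = O * Tc
        if self.reverse:
            return hs[:, ::-1, :]
        return hs

    def backward(self, dy):
        if self.reverse:
            dy = dy[:, ::-1, :]
        x, I, Fg, G, O, Cs, Tc, Hprev, Cprev = self._cache
        B, T, F = x.shape
        H = self.h
        dz_all = np.empty((B, T, 4 * H), dtype=dy.dtype)
        dh_next = np.zeros((B, H), dtype=dy.dtype)
        dc_next = np.zeros((B, H), dtype=dy.dtype)
        WhT = self.Wh.T
        for t in range(T - 1, -1, -1):
            dh = dy[:, t] + dh_next
            i, f, g, o = I[:, t], Fg[:, t], G[:, t], O[:, t]
            tc = Tc[:, t]
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * Cprev[:, t]
            dg = dc * i
            dzi = di * i * (1.0 - i)
            dzf = df * f * (1.0 - f)
            dzg = dg * (1.0 - g * g)
            dzo = do * o * (1.0 - o)
            dz = np.concatenate([dzi, dzf, dzg, dzo], axis=1)
            dz_all[:, t] = dz
            dh_next = dz @ WhT
            dc_next = dc * f
        flat_dz = dz_all.reshape(-1, 4 * H)
        self.dWx = x.reshape(-1, F).T @ flat_dz
        self.dWh = Hprev.reshape(-1, H).T @ flat_dz
        self.db = flat_dz.sum(axis=0)
        dx = (flat_dz @ self.Wx.T).reshape(B, T, F)
        if self.reverse:
            return dx[:, ::-1, :]
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM: concatenates forward and backward hidden sequences,
    so the per-frame output width is twice the per-direction hidden width."""

    def __init__(self, in_features: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        self.h = hidden
        self.fwd = LSTM(in_features, hidden, rng, reverse=False, dtype=dtype)
        self.bwd = LSTM(in_features, hidden, rng, reverse=True, dtype=dtype)

    def params(self):
        out = {}
        for prefix, sub in (("fwd", self.fwd), ("bwd", self.bwd)):
            for k, v in sub.params().items():
                out[f"{prefix}.{k}"] = v
        return out

    def grads(self):
        out = {}
        for prefix, sub in (("fwd", self.fwd), ("bwd", self.bwd)):
            for k, v in sub.grads().items():
                out[f"{prefix}.{k}"] = v
        return out

    def forward(self, x):
        return np.concatenate([self.fwd.forward(x), self.bwd.forward(x)], axis=2)

    def backward(self, dy):
        H = self.h
        return self.fwd.backward(dy[:, :, :H]) + self.bwd.backward(dy[:, :, H:])


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self):
        out = {}
        for idx, layer in enumerate(self.layers):
            for k, v in layer.params().items():
                out[f"{idx}.{k}"] = v
        return out

    def grads(self):
        out = {}
        for idx, layer in enumerate(self.layers):
            for k, v in layer.grads().items():
                out[f"{idx}.{k}"] = v
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam with the usual bias correction; operates on a Layer's params/grads."""

    def __init__(self, model: Layer, learning_rate: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.model = model
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in model.params().items()}
        self.v = {k: np.zeros_like(v) for k, v in model.params().items()}

    def step(self) -> None:
        self.t += 1
        params = self.model.params()
        grads = self.model.grads()
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1.0 - b1) * g
            self.v[k] = b2 * self.v[k] + (1.0 - b2) * g * g
            p -= self.lr * (self.m[k] / bias1) / (np.sqrt(self.v[k] / bias2) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, (2.0 / diff.size) * diff


def bce_with_logits_loss(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy on logits; labels in {0, 1}."""
    z = logits
    y = labels
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    sig = 1.0 / (1.0 + np.exp(-z))
    return loss, (sig - y) / z.size


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
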
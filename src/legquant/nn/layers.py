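"""Layers with explicit forward/backward passes (float32, NCHW)."""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d", "Upsample2d",
    "Linear", "GlobalAvgPool",
]


class Layer:
    """Base class: subclasses implement forward/backward and expose
    ``params`` as a list of (name, value-array, grad-array) triples."""

    train_mode: bool = True

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) with same-padding, stride 1."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols)


def _conv_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 same-pad correlation; w is (cout, cin, k, k)."""
    n, c, h, wd = x.shape
    cout, cin, k, _ = w.shape
    cols = _im2col(x, k)
    out = cols @ w.reshape(cout, cin * k * k).T
    return out.reshape(n, h, wd, cout).transpose(0, 3, 1, 2)


class Conv2d(Layer):
    """k x k correlation, stride 1, same padding, He-initialized."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = (rng.normal(0, scale, (cout, cin, k, k))).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.k = k

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def forward(self, x):
        n, c, h, wd = x.shape
        cout = self.w.shape[0]
        cols = _im2col(x, self.k)
        if self.train_mode:
            self._cols = cols  # reused for the weight gradient
        y = cols @ self.w.reshape(cout, -1).T
        y = y.reshape(n, h, wd, cout).transpose(0, 3, 1, 2)
        return y + self.b[None, :, None, None]

    def backward(self, dy):
        n, cout, h, w = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * h * w, cout)
        self.dw[...] = (dyf.T @ self._cols).reshape(self.w.shape)
        self._cols = None
        self.db[...] = dyf.sum(axis=0)
        w_flip = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (cin, cout, k, k)
        return _conv_raw(dy, np.ascontiguousarray(w_flip))


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def forward(self, x):
        if self.train_mode:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._xhat = (x - mean[None, :, None, None]) * self._inv[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dy):
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma[...] = (dy * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dy.sum(axis=(0, 2, 3))
        if not self.train_mode:
            return dy * (self.gamma * self._inv)[None, :, None, None]
        g = self.gamma[None, :, None, None]
        dxhat = dy * g
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        )
        return term * self._inv[None, :, None, None]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling; H and W must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        self._mask = xr == y[:, :, :, None, :, None]
        # break ties deterministically: keep only first max per window
        flat = self._mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        self._mask = (flat & first).reshape(n, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5
        )
        return y

    def backward(self, dy):
        n, c, hh, ww = dy.shape
        dx = self._mask * dy[:, :, :, None, :, None]
        return dx.reshape(n, c, hh * 2, ww * 2)


class Upsample2d(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / cin)
        self.w = rng.normal(0, scale, (cout, cin)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def forward(self, x):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy):
        self.dw[...] = dy.T @ self._x
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)
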
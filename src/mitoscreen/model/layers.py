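"""Minimal trainable layers (1-D convolution with dilation, dense) with
explicit forward/backward passes and an Adam optimizer.

Shapes follow the (batch, channels, length) convention throughout.
"""
from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, kernel: int, dilation: int) -> np.ndarray:
    """(B, C, L) -> (B, C*kernel, L_out) patch matrix for a valid conv."""
    B, C, L = x.shape
    span = (kernel - 1) * dilation + 1
    L_out = L - span + 1
    taps = np.arange(0, span, dilation)  # (kernel,)
    idx = taps[:, None] + np.arange(L_out)[None, :]  # (kernel, L_out)
    cols = x[:, :, idx]  # (B, C, kernel, L_out)
    return cols.reshape(B, C * kernel, L_out)


class Conv1D:
    """Cross-correlation conv with optional zero 'same' padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int = 1,
                 pad_same: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.kernel, self.dilation = c_in, c_out, kernel, dilation
        self.pad = ((kernel - 1) * dilation) // 2 if pad_same else 0
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * kernel)).astype(np.float64)
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        cols = _im2col(x, self.kernel, self.dilation)
        y = np.einsum("ok,bkl->bol", self.W, cols) + self.b[None, :, None]
        self._cache = (cols, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        B, _, L_pad = x_shape
        self.dW += np.einsum("bol,bkl->ok", dy, cols)
        self.db += dy.sum(axis=(0, 2))
        dcols = np.einsum("ok,bol->bkl", self.W, dy)  # (B, C*kernel, L_out)
        dcols = dcols.reshape(B, self.c_in, self.kernel, -1)
        dx = np.zeros((B, self.c_in, L_pad))
        L_out = dcols.shape[-1]
        for t in range(self.kernel):
            dx[:, :, t * self.dilation : t * self.dilation + L_out] += dcols[:, :, t, :]
        if self.pad:
            dx = dx[:, :, self.pad : -self.pad]
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += dy.T @ self._x
        self.db += dy.sum(axis=0)
        return dy @ self.W

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)

    def params(self):
        return []


class Adam:
    """Adaptive-moment optimizer over a flat (param, grad) list."""

    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0
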
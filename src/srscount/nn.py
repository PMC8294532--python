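"""Minimal NumPy convolutional-network backend.

Implements exactly the layer set the reduced U-Net needs — same-padding
3x3/1x1 convolutions, 2x2 max pooling, 2x2 stride-2 transposed
convolutions, ReLU — with hand-derived backward passes, a binary
cross-entropy-with-logits loss, and the Adam optimiser.  Arrays are
channels-last (NHWC) float32; convolutions are lowered to BLAS matmuls
via im2col (``sliding_window_view``), and the data gradient of a
same-padding convolution is computed as a convolution with the
spatially flipped, in/out-transposed kernel, so every heavy operation
is a single large matmul.

All randomness is drawn from explicitly passed ``numpy`` generators, so
identical seeds give bit-identical training runs on a fixed machine.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, k*k*C) patch matrix for a same-padding k x k conv."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,C,k,k)
    win = win.transpose(0, 1, 2, 4, 5, 3)               # (N,H,W,k,k,C)
    n, h, w = x.shape[:3]
    return win.reshape(n * h * w, k * k * x.shape[3])


class Conv2D:
    """Same-padding k x k convolution (k odd), He-initialised."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = k * k * c_in
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.w = (rng.standard_normal((k * k * c_in, c_out))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, _ = x.shape
        if self.k == 1:
            if train:
                self._x = x
            y = x.reshape(-1, self.c_in) @ self.w + self.b
        else:
            cols = _im2col(x, self.k)
            if train:
                self._x, self._cols = x, cols
            y = cols @ self.w + self.b
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, h, w, _ = x.shape
        dyf = dy.reshape(-1, self.c_out)
        if self.k == 1:
            self.dw[:] = x.reshape(-1, self.c_in).T @ dyf
            self.db[:] = dyf.sum(axis=0)
            dx = (dyf @ self.w.T).reshape(x.shape)
        else:
            cols, self._cols = self._cols, None
            self.dw[:] = cols.T @ dyf
            self.db[:] = dyf.sum(axis=0)
            # data gradient = same-padding conv of dy with the rotated,
            # in/out-swapped kernel
            wt = self.w.reshape(self.k, self.k, self.c_in, self.c_out)
            wr = wt[::-1, ::-1].transpose(0, 1, 3, 2).reshape(
                self.k * self.k * self.c_out, self.c_in)
            dx = (_im2col(dy, self.k) @ wr).reshape(x.shape)
        self._x = None
        return dx

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling, stride 2 (spatial dims must be even)."""

    def __init__(self):
        self._idx: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max pooling needs even spatial dims, got {h}x{w}")
        q = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        q = q.reshape(n, h // 2, w // 2, 4, c)
        idx = q.argmax(axis=3)
        y = np.take_along_axis(q, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._idx, self._shape = idx, (n, h, w, c)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        g = np.zeros((n, h // 2, w // 2, 4, c), dtype=dy.dtype)
        np.put_along_axis(g, self._idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = g.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        self._idx = self._shape = None
        return dx.reshape(n, h, w, c)

    def params(self):
        return []


class UpConv2:
    """2x2 stride-2 transposed convolution (doubles spatial size)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.w = (rng.standard_normal((4, c_in, c_out))
                  * np.sqrt(2.0 / c_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        n, h, w, _ = x.shape
        xf = x.reshape(-1, self.c_in)
        y = np.empty((n, 2 * h, 2 * w, self.c_out), dtype=np.float32)
        for o, (di, dj) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
            y[:, di::2, dj::2, :] = (xf @ self.w[o]).reshape(n, h, w, self.c_out)
        y += self.b
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, h, w, _ = x.shape
        xf = x.reshape(-1, self.c_in)
        dx = np.zeros((n * h * w, self.c_in), dtype=np.float32)
        self.db[:] = dy.sum(axis=(0, 1, 2))
        for o, (di, dj) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
            dyo = dy[:, di::2, dj::2, :].reshape(-1, self.c_out)
            self.dw[o] = xf.T @ dyo
            dx += dyo @ self.w[o].T
        self._x = None
        return dx.reshape(x.shape)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


def bce_with_logits(logits: np.ndarray, targets: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Mean pixel-wise binary cross-entropy and its gradient w.r.t. logits."""
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = 1.0 / (1.0 + np.exp(-z))
    dz = ((p - y) / z.size).astype(np.float32)
    return loss, dz


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam with bias-corrected first/second moment estimates."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
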
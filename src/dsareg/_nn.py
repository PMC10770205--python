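"""Minimal convolutional building blocks (numpy, float32).

Implements exactly the pieces the landmark detector needs — 3x3 "same"
convolution via im2col + GEMM, ReLU, 2x2 max pooling, nearest-neighbour
2x upsampling, channel concatenation and an Adam optimizer — with
hand-written backward passes.  Tensors are (N, C, H, W) float32.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Conv3x3:
    """3x3 convolution, stride 1, zero "same" padding.

    Parameters: weight (cout, cin*9) and bias (cout,); He-normal init.
    Parameter count = 9*cin*cout + cout.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / (9 * cin))
        self.w = rng.normal(0.0, std, size=(cout, cin * 9)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        # (n, c, h, w, 3, 3) -> (n, c*9, h*w)
        return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(n, c * 9, h * w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        out = np.matmul(self.w, cols) + self.b[:, None]
        self._cache = (cols, x.shape)
        return out.reshape(n, self.cout, h, w)

    def backward(self, dout: np.ndarray):
        cols, (n, c, h, w) = self._cache
        dflat = dout.reshape(n, self.cout, h * w)
        self.dw = np.einsum("nof,ncf->oc", dflat, cols).astype(DTYPE)
        self.db = dflat.sum(axis=(0, 2)).astype(DTYPE)
        dcols = np.matmul(self.w.T, dflat)  # (n, c*9, h*w)
        dcols = dcols.reshape(n, c, 3, 3, h, w)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=DTYPE)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, i, j]
        return dxp[:, :, 1:-1, 1:-1]

    def grads(self):
        return [self.dw, self.db]


class Conv1x1:
    """1x1 convolution (per-pixel linear map). Parameter count = cin*cout + cout."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / cin)
        self.w = rng.normal(0.0, std, size=(cout, cin)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.einsum("oc,nchw->nohw", self.w, x) + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray):
        self.dw = np.einsum("nohw,nchw->oc", dout, self._x).astype(DTYPE)
        self.db = dout.sum(axis=(0, 2, 3)).astype(DTYPE)
        return np.einsum("oc,nohw->nchw", self.w, dout)

    def grads(self):
        return [self.dw, self.db]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2.  Input H, W must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        out = win.max(axis=-1)
        idx = win.argmax(axis=-1)  # first max wins on ties
        self._onehot = idx[..., None] == np.arange(4)
        self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dwin = self._onehot * dout[..., None]
        dx = dwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx).reshape(n, c, h, w)


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place updates)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
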
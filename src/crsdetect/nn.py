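"""Minimal CNN building blocks in numpy.

Stride-1 "same"-padded 2D convolution (via im2col and BLAS matmuls),
leaky ReLU, 2×1 max pooling, dense layers, inverted dropout, a fused
softmax / categorical cross-entropy head, and Adam.  Everything runs in
float32 and is exactly reproducible given a seeded Generator: weight
initialization, batch shuffling and dropout masks all draw from the
caller's RNG, and no threading-dependent reductions are used beyond
BLAS matmul.

Gradient correctness is pinned by finite-difference tests; this module
deliberately implements only what the gesture classifier needs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "LeakyReLU",
    "MaxPool2x1",
    "Flatten",
    "Dense",
    "Dropout",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


class Layer:
    """Interface: forward(x, train) -> y; backward(dy) -> dx; params/grads lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 convolution with "same" zero padding, odd kernels only.

    Input layout (B, H, W, C); weights (kh*kw*C, F) so both the forward
    pass and the weight gradient are single matmuls over im2col patches.
    """

    def __init__(self, in_ch: int, out_ch: int, kh: int, kw: int, rng: np.random.Generator):
        super().__init__()
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel dims must be odd for same padding")
        self.in_ch, self.out_ch, self.kh, self.kw = in_ch, out_ch, kh, kw
        fan_in = kh * kw * in_ch
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, out_ch))
        self.w = w.astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._cols: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def _im2col(self, x: np.ndarray, kh: int, kw: int) -> np.ndarray:
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        # (B, H, W, C, kh, kw) -> (B*H*W, kh*kw*C)
        win = sliding_window_view(xp, (kh, kw), axis=(1, 2))
        b, h, w = x.shape[0], x.shape[1], x.shape[2]
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(b * h * w, kh * kw * x.shape[3])
        return np.ascontiguousarray(cols, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, _ = x.shape
        cols = self._im2col(x, self.kh, self.kw)
        y = cols @ self.w + self.b
        if train:
            self._cols = cols
            self._in_shape = x.shape
        return y.reshape(b, h, w, self.out_ch)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, f = dy.shape
        dy_flat = dy.reshape(b * h * w, f).astype(np.float32)
        np.matmul(self._cols.T, dy_flat, out=self.grads[0])
        self.grads[1][...] = dy_flat.sum(axis=0)
        # dx = same-padded correlation of dy with the flipped kernel,
        # input/output channels swapped
        wk = self.w.reshape(self.kh, self.kw, self.in_ch, self.out_ch)
        wk = wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(
            self.kh * self.kw * self.out_ch, self.in_ch
        )
        cols_dy = self._im2col(dy, self.kh, self.kw)
        dx = cols_dy @ np.ascontiguousarray(wk)
        self._cols = None
        return dx.reshape(self._in_shape)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = float(slope)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.where(x >= 0, x, self.slope * x)
        if train:
            self._mask = x >= 0
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy).astype(np.float32)


class MaxPool2x1(Layer):
    """Max pool with window (2, 1): halves the time axis, keeps sensors."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, c = x.shape
        if h % 2:
            raise ValueError(f"time axis must be even for 2x1 pooling, got {h}")
        xr = x.reshape(b, h // 2, 2, w, c)
        idx = xr.argmax(axis=2)
        y = xr.max(axis=2)
        if train:
            self._idx = idx
            self._in_shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h2, w, c = dy.shape
        dx = np.zeros((b, h2, 2, w, c), dtype=np.float32)
        bi, hi, wi, ci = np.ogrid[:b, :h2, :w, :c]
        dx[bi, hi, self._idx, wi, ci] = dy
        return dx.reshape(self._in_shape)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.w = rng.normal(0.0, np.sqrt(2.0 / in_dim), (in_dim, out_dim)).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy.astype(np.float32)
        np.matmul(self._x.T, dy, out=self.grads[0])
        self.grads[1][...] = dy.sum(axis=0)
        self._x = None
        return dy @ self.w.T


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not (0.0 <= p < 1.0):
            raise ValueError(f"dropout rate must lie in [0, 1), got {p}")
        self.p = float(p)
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, onehot: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-(onehot * np.log(np.clip(p, 1e-12, None))).sum() / n)
    grad = ((p - onehot) / n).astype(np.float32)
    return loss, grad


class Adam:
    """Adam with the standard bias correction (β1=0.9, β2=0.999)."""

    def __init__(self, layers, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self._tmp = [[np.empty_like(p) for p in l.params] for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                tmp = self._tmp[li][pi]
                # in-place update via one scratch buffer (these arrays hold
                # ~10M floats; avoiding temporaries dominates step cost)
                m *= self.beta1
                np.multiply(g, 1.0 - self.beta1, out=tmp)
                m += tmp
                v *= self.beta2
                np.multiply(g, g, out=tmp)
                tmp *= 1.0 - self.beta2
                v += tmp
                np.sqrt(v, out=tmp)
                tmp *= 1.0 / np.sqrt(b2t)
                tmp += self.eps
                np.divide(m, tmp, out=tmp)
                tmp *= self.lr / b1t
                p -= tmp
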
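"""Minimal CPU neural-network layers for the UNet segmenter.

Float32, channels-last (N, H, W, C) layout throughout.  Convolutions are
evaluated as im2col + BLAS matrix products, which is where virtually all
training time is spent; the input-gradient pass reuses the same
primitive as a full convolution with the spatially flipped kernel.

Only what the segmenter needs is implemented: k x k "same" convolution,
batch normalization, ReLU, 2x2 max pooling, 2x nearest-neighbour
upsampling and an Adam optimizer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, C*k*k) patch matrix with 'same' zero padding."""
    if k == 1:
        n, h, w, c = x.shape
        return x.reshape(n * h * w, c)
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,C,k,k)
    n, h, w, c = x.shape
    return np.ascontiguousarray(win).reshape(n * h * w, c * k * k)


class Conv:
    """k x k convolution with 'same' padding (He-initialized)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, c_out)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        n, h, w, _ = x.shape
        y = _im2col(x, self.k) @ self.w + self.b
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray):
        x = self._x
        n, h, w, _ = x.shape
        dy_flat = dy.reshape(n * h * w, self.c_out)
        col = _im2col(x, self.k)
        dw = col.T @ dy_flat
        db = dy_flat.sum(axis=0)
        # input gradient = full correlation of dy with the flipped kernel
        wk = self.w.reshape(self.c_in, self.k, self.k, self.c_out)
        w_flip = wk[:, ::-1, ::-1, :].transpose(3, 1, 2, 0)  # (Cout,k,k,Cin)
        w_back = np.ascontiguousarray(w_flip).reshape(self.c_out * self.k * self.k, self.c_in)
        dx = (_im2col(dy, self.k) @ w_back).reshape(x.shape)
        self._x = None
        return dx, [dw, db]


class BatchNorm:
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.run_mean = np.zeros(c, dtype=F32)
        self.run_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv.astype(F32))
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray):
        xhat, inv = self._cache
        self._cache = None
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        dgamma = (dy * xhat).sum(axis=(0, 1, 2))
        dbeta = dy.sum(axis=(0, 1, 2))
        dx = (self.gamma * inv / m) * (m * dy - dbeta - xhat * dgamma)
        return dx.astype(F32), [dgamma, dbeta]


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, F32(0))
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray):
        dx = np.where(self._mask, dy, F32(0))
        self._mask = None
        return dx, []


class MaxPool2:
    def __init__(self):
        self._idx = None
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        win = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        flat = win.reshape(n, h // 2, w // 2, c, 4)
        if train:
            self._idx = flat.argmax(axis=-1)
            self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy: np.ndarray):
        n, h2, w2, c = dy.shape
        scatter = np.zeros((n, h2, w2, c, 4), dtype=F32)
        np.put_along_axis(scatter, self._idx[..., None], dy[..., None], axis=-1)
        dx = scatter.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx = dx.reshape(self._shape)
        self._idx = None
        return np.ascontiguousarray(dx), []


class Upsample2:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray):
        n, h, w, c = dy.shape
        dx = dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))
        return np.ascontiguousarray(dx), []


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * (g * g)
            p -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(p.dtype)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def dice_bce_loss(logits: np.ndarray, targets: np.ndarray, eps: float = 1.0):
    """Soft-Dice + binary cross-entropy loss and its logit gradient.

    Dice is computed per sample and averaged; BCE is averaged per pixel.
    Returns ``(loss, dlogits)``.
    """
    p = sigmoid(logits.astype(np.float64))
    y = targets.astype(np.float64)
    n = logits.shape[0]
    npix = y[0].size
    # BCE (numerically stable in logit form)
    z = logits.astype(np.float64)
    bce = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    dz_bce = (p - y) / (n * npix)
    # soft Dice per sample
    axes = tuple(range(1, y.ndim))
    inter = (p * y).sum(axis=axes)
    sums = p.sum(axes) + y.sum(axes)
    dice = (2 * inter + eps) / (sums + eps)
    dloss_dp = -(2 * y * (sums + eps)[..., None, None, None]
                 - (2 * inter + eps)[..., None, None, None]) / (sums + eps)[..., None, None, None] ** 2
    dz_dice = dloss_dp * p * (1 - p) / n
    loss = float(bce + np.mean(1 - dice))
    return loss, (dz_bce + dz_dice).astype(F32)
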
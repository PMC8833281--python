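"""Minimal NumPy convolutional-network engine for 2D segmentation.

Implements exactly the pieces the encoder-decoder segmenter needs — 3x3
same-padding convolution, 2x2 max pooling, 2x2 stride-2 transposed
convolution, 1x1 convolution, ReLU/sigmoid, skip concatenation, soft-Dice
loss and Adam — with hand-written gradients.  Convolutions are evaluated as
im2col + BLAS matmul in float32; activations use the NHWC layout
(batch, height, width, channels) throughout.

Everything is deterministic given the initializer seed: there is no dropout,
no batch statistics, and no multi-threaded reduction inside a training run.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = ["Conv3x3", "Conv1x1", "MaxPool2", "ConvTranspose2x2", "Adam", "dice_loss"]

_F32 = np.float32


def _he_normal(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(_F32)


class Layer:
    """Base: parameters and their gradients as parallel lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Conv3x3(Layer):
    """3x3 convolution, stride 1, same padding, optional fused ReLU.

    Weights are stored as (c_in * 9, c_out) in (channel, row, col) tap order,
    matching the flattened im2col window layout.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, relu: bool = True):
        self.c_in, self.c_out, self.relu = c_in, c_out, relu
        self.w = _he_normal(rng, 9 * c_in, (c_in * 9, c_out))
        self.b = np.zeros(c_out, dtype=_F32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (n, h, w, c, 3, 3)
        return np.ascontiguousarray(cols).reshape(n * h * w, c * 9)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        self._cols = self._im2col(x)
        y = self._cols @ self.w
        y += self.b
        y = y.reshape(n, h, w, self.c_out)
        if self.relu:
            self._mask = y > 0
            y = np.where(self._mask, y, _F32(0))
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, h, w, _ = g.shape
        if self.relu:
            g = np.where(self._mask, g, _F32(0))
        gf = g.reshape(n * h * w, self.c_out)
        self.grads[0][...] = self._cols.T @ gf
        self.grads[1][...] = gf.sum(axis=0)
        # dX is a full correlation of g with the spatially flipped kernel
        w4 = self.w.reshape(self.c_in, 3, 3, self.c_out)
        w_back = w4[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(self.c_out * 9, self.c_in)
        gcols = self._im2col(g)
        dx = (gcols @ w_back).reshape(n, h, w, self.c_in)
        self._cols = None
        return dx


class Conv1x1(Layer):
    """1x1 convolution with optional fused sigmoid (the output head)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, sigmoid: bool = True):
        self.c_in, self.c_out, self.sigmoid = c_in, c_out, sigmoid
        self.w = _he_normal(rng, c_in, (c_in, c_out))
        self.b = np.zeros(c_out, dtype=_F32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.w + self.b
        if self.sigmoid:
            self._out = expit(y).astype(_F32)
            return self._out
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.sigmoid:
            g = g * self._out * (1.0 - self._out)
        n, h, w, _ = g.shape
        gf = g.reshape(-1, self.c_out).astype(_F32)
        xf = self._x.reshape(-1, self.c_in)
        self.grads[0][...] = xf.T @ gf
        self.grads[1][...] = gf.sum(axis=0)
        dx = (gf @ self.w.T).reshape(n, h, w, self.c_in)
        self._x = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2.  Tied maxima share the gradient equally."""

    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        mask = xr == y[:, :, None, :, None, :]
        self._mask = (mask / mask.sum(axis=(2, 4), keepdims=True)).astype(_F32)
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, hh, ww, c = g.shape
        gx = self._mask * g[:, :, None, :, None, :]
        self._mask = None
        return gx.reshape(n, hh * 2, ww * 2, c).astype(_F32)


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution with stride 2 (each input pixel emits a
    2x2 output block), optional fused ReLU.  Doubles the spatial size."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, relu: bool = True):
        self.c_in, self.c_out, self.relu = c_in, c_out, relu
        self.w = _he_normal(rng, c_in, (c_in, c_out * 4))
        self.b = np.zeros(c_out, dtype=_F32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._xf = x.reshape(n * h * w, c)
        y = (self._xf @ self.w).reshape(n, h, w, self.c_out, 2, 2)
        y = y.transpose(0, 1, 4, 2, 5, 3).reshape(n, 2 * h, 2 * w, self.c_out)
        y = y + self.b
        if self.relu:
            self._mask = y > 0
            y = np.where(self._mask, y, _F32(0))
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, hh, ww, _ = g.shape
        h, w = hh // 2, ww // 2
        if self.relu:
            g = np.where(self._mask, g, _F32(0))
        self.grads[1][...] = g.sum(axis=(0, 1, 2))
        gb = (
            g.reshape(n, h, 2, w, 2, self.c_out)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n * h * w, self.c_out * 4)
        )
        gb = np.ascontiguousarray(gb)
        self.grads[0][...] = self._xf.T @ gb
        dx = (gb @ self.w.T).reshape(n, h, w, self.c_in)
        self._xf = None
        return dx


class Adam:
    """Adam optimizer over an explicit parameter/gradient list."""

    def __init__(self, layers: list[Layer], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.pairs = [(p, g) for layer in layers for p, g in zip(layer.params, layer.grads)]
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def dice_loss(
    pred: np.ndarray, truth: np.ndarray, smooth_eps: float = 1.0, with_grad: bool = False
):
    """Soft-Dice loss ``1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps)``.

    The smoothing term appears in both numerator and denominator so the loss
    is defined (and zero) when prediction and truth are both empty.  Bounded
    in [0, 1).

    Parameters
    ----------
    pred : probabilities in [0, 1], any shape.
    truth : binary array, same shape.
    smooth_eps : the smoothing constant (> 0).
    with_grad : if True, also return d(loss)/d(pred).

    Raises
    ------
    ValueError
        On shape mismatch or non-positive ``smooth_eps``.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if smooth_eps <= 0:
        raise ValueError("smooth_eps must be > 0")
    inter = float((pred * truth).sum())
    denom = float(pred.sum() + truth.sum()) + smooth_eps
    loss = 1.0 - (2.0 * inter + smooth_eps) / denom
    if not with_grad:
        return loss
    grad = -(2.0 * truth * denom - (2.0 * inter + smooth_eps)) / denom**2
    return loss, grad.astype(_F32)
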
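"""Minimal CPU neural-network primitives (forward + backward + Adam).

Just the pieces the hashing model needs: 3×3 strided convolution, ReLU,
fully connected layers and ×2 nearest-neighbour upsampling, each as a pure
function pair ``*_forward`` (returning output and a cache) and
``*_backward`` (returning input and parameter gradients).

Activations are channels-last ``(B, H, W, C)`` float32. Convolutions are
computed as a sum over the nine kernel taps, each tap a single large GEMM —
on a CPU this keeps the working set small and lets BLAS do all the work.
Everything is deterministic for a fixed parameter state and input.
"""

from __future__ import annotations

import numpy as np

__all__ = ["conv2d_forward", "conv2d_backward", "linear_forward",
           "linear_backward", "relu_forward", "relu_backward",
           "upsample2_forward", "upsample2_backward", "he_init", "Adam"]


def he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _tap_slices(i: int, j: int, ho: int, wo: int, stride: int):
    return (slice(i, i + (ho - 1) * stride + 1, stride),
            slice(j, j + (wo - 1) * stride + 1, stride))


def conv2d_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray,
                   stride: int = 1):
    """3×3 convolution, padding 1.

    x: (B, H, W, C); weight: (3, 3, C, O); bias: (O,).
    Returns y (B, H', W', O) and the backward cache.
    """
    b, h, w, c = x.shape
    o = weight.shape[3]
    ho = (h - 1) // stride + 1
    wo = (w - 1) // stride + 1
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    yf = np.tile(bias.astype(x.dtype), (b * ho * wo, 1))
    for i in range(3):
        for j in range(3):
            si, sj = _tap_slices(i, j, ho, wo, stride)
            xs = np.ascontiguousarray(xp[:, si, sj, :]).reshape(-1, c)
            yf += xs @ weight[i, j]
    y = yf.reshape(b, ho, wo, o)
    return y, (xp, x.shape, stride, (ho, wo))


def conv2d_backward(dy: np.ndarray, cache, weight: np.ndarray):
    xp, x_shape, stride, (ho, wo) = cache
    b, h, w, c = x_shape
    o = weight.shape[3]
    dyf = np.ascontiguousarray(dy).reshape(-1, o)
    dweight = np.empty_like(weight)
    dxp = np.zeros_like(xp)
    for i in range(3):
        for j in range(3):
            si, sj = _tap_slices(i, j, ho, wo, stride)
            xs = np.ascontiguousarray(xp[:, si, sj, :]).reshape(-1, c)
            dweight[i, j] = xs.T @ dyf
            dxp[:, si, sj, :] += (dyf @ weight[i, j].T).reshape(b, ho, wo, c)
    dbias = dyf.sum(axis=0)
    return dxp[:, 1:-1, 1:-1, :], dweight, dbias


def linear_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """x: (B, I); weight: (O, I); bias: (O,)."""
    return x @ weight.T + bias, x


def linear_backward(dy: np.ndarray, cache, weight: np.ndarray):
    x = cache
    return dy @ weight, dy.T @ x, dy.sum(axis=0)


def relu_forward(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(dy: np.ndarray, mask: np.ndarray):
    return dy * mask


def upsample2_forward(x: np.ndarray):
    """Nearest-neighbour ×2 upsampling of (B, H, W, C)."""
    return x.repeat(2, axis=1).repeat(2, axis=2), x.shape


def upsample2_backward(dy: np.ndarray, x_shape):
    b, h, w, c = x_shape
    return dy.reshape(b, h, 2, w, 2, c).sum(axis=(2, 4))


class Adam:
    """Adam optimiser over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            mhat = self.m[k] / b1c
            vhat = self.v[k] / b2c
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
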
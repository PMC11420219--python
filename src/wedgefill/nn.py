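"""Minimal NumPy engine for volumetric convolutional networks.

Implements exactly the pieces the fitting loop needs - 3D convolutions,
2x2x2 transposed convolutions and max-pooling, leaky ReLU, dropout, and
Adam - with hand-written backward passes.  Convolutions use a
shift-and-GEMM decomposition in a channels-last layout ``(B, D, H, W, C)``:
one BLAS matmul per kernel offset, which keeps single-core throughput
close to peak without materializing im2col buffers.

Layers cache what their backward pass needs on ``forward``; a layer
supports one in-flight forward/backward at a time, which is all the
training loop requires.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv3d",
    "ConvTranspose3d",
    "MaxPool3d",
    "LeakyReLU",
    "Dropout",
    "Adam",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []


def _offsets(k: int):
    return [(a, b, c) for a in range(k) for b in range(k) for c in range(k)]


class Conv3d(Layer):
    """Same-size 3D convolution with odd kernel size (1 or 3 in practice)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        fan_in = in_ch * kernel ** 3
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU-family
        w = rng.standard_normal((kernel ** 3, in_ch, out_ch)) * scale
        self.weight = Param(w.astype(dtype))
        self.bias = Param(np.zeros(out_ch, dtype=dtype))
        self.kernel = kernel
        self.in_ch, self.out_ch = in_ch, out_ch
        self._xpad: np.ndarray | None = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.kernel, self.kernel // 2
        if k == 1:
            self._xpad = x
            return x @ self.weight.value[0] + self.bias.value
        B, D, H, W, _ = x.shape
        xpad = np.zeros((B, D + 2 * p, H + 2 * p, W + 2 * p, self.in_ch),
                        dtype=x.dtype)
        xpad[:, p:p + D, p:p + H, p:p + W] = x
        self._xpad = xpad
        out = np.zeros((B, D, H, W, self.out_ch), dtype=x.dtype)
        for i, (a, b, c) in enumerate(_offsets(k)):
            out += xpad[:, a:a + D, b:b + H, c:c + W] @ self.weight.value[i]
        out += self.bias.value
        return out

    def backward(self, gy: np.ndarray, need_input_grad: bool = True
                 ) -> np.ndarray | None:
        k, p = self.kernel, self.kernel // 2
        xpad = self._xpad
        assert xpad is not None
        self.bias.grad += gy.sum(axis=(0, 1, 2, 3))
        if k == 1:
            n = xpad.shape[-1]
            self.weight.grad[0] += (xpad.reshape(-1, n).T
                                    @ gy.reshape(-1, self.out_ch))
            return gy @ self.weight.value[0].T if need_input_grad else None
        B, D, H, W, _ = gy.shape
        gy2d = np.ascontiguousarray(gy).reshape(-1, self.out_ch)
        for i, (a, b, c) in enumerate(_offsets(k)):
            view = np.ascontiguousarray(xpad[:, a:a + D, b:b + H, c:c + W])
            self.weight.grad[i] += view.reshape(-1, self.in_ch).T @ gy2d
        self._xpad = None
        if not need_input_grad:
            return None
        # d loss / d input is a convolution of gy with the flipped kernels
        gypad = np.zeros((B, D + 2 * p, H + 2 * p, W + 2 * p, self.out_ch),
                         dtype=gy.dtype)
        gypad[:, p:p + D, p:p + H, p:p + W] = gy
        gx = np.zeros((B, D, H, W, self.in_ch), dtype=gy.dtype)
        last = k ** 3 - 1
        for i, (a, b, c) in enumerate(_offsets(k)):
            gx += gypad[:, a:a + D, b:b + H, c:c + W] @ self.weight.value[last - i].T
        return gx


class ConvTranspose3d(Layer):
    """Stride-2, kernel-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / in_ch)
        w = rng.standard_normal((8, in_ch, out_ch)) * scale
        self.weight = Param(w.astype(dtype))
        self.bias = Param(np.zeros(out_ch, dtype=dtype))
        self.in_ch, self.out_ch = in_ch, out_ch
        self._x: np.ndarray | None = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        B, D, H, W, _ = x.shape
        out = np.empty((B, 2 * D, 2 * H, 2 * W, self.out_ch), dtype=x.dtype)
        for i, (a, b, c) in enumerate(_offsets(2)):
            out[:, a::2, b::2, c::2] = x @ self.weight.value[i]
        out += self.bias.value
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        self.bias.grad += gy.sum(axis=(0, 1, 2, 3))
        gx = np.zeros_like(x)
        for i, (a, b, c) in enumerate(_offsets(2)):
            sub = gy[:, a::2, b::2, c::2]
            self.weight.grad[i] += np.tensordot(x, sub, axes=([0, 1, 2, 3],) * 2)
            gx += sub @ self.weight.value[i].T
        self._x = None
        return gx


class MaxPool3d(Layer):
    """2x2x2 max pooling."""

    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, D, H, W, C = x.shape
        xr = x.reshape(B, D // 2, 2, H // 2, 2, W // 2, 2, C)
        out = xr.max(axis=(2, 4, 6))
        self._mask = xr == out[:, :, None, :, None, :, None, :]
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        mask = self._mask
        assert mask is not None
        g = mask * gy[:, :, None, :, None, :, None, :]
        self._mask = None
        B, d, _, h, _, w, _, C = g.shape
        return g.reshape(B, 2 * d, 2 * h, 2 * w, C)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1):
        self.slope = slope
        self._neg: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        neg = x < 0
        self._neg = neg
        return np.where(neg, x * np.asarray(self.slope, dtype=x.dtype), x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        neg = self._neg
        assert neg is not None
        self._neg = None
        return np.where(neg, gy * np.asarray(self.slope, dtype=gy.dtype), gy)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(x.dtype)
        keep /= np.asarray(1.0 - self.p, dtype=x.dtype)
        self._mask = keep
        return x * keep

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gy
        g = gy * self._mask
        self._mask = None
        return g


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
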
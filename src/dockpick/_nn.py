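"""Compact plain-numpy neural-network core.

Layers carry explicit ``forward``/``backward`` passes and learnable
:class:`Param` tensors; :class:`Adam` optimizes a flat parameter list.
Volumetric data follows the (batch, channel, depth, height, width)
convention. All arithmetic is float32; convolutions are evaluated as
im2col matrix products so the heavy lifting stays inside BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "ReLU",
    "Flatten",
    "Linear",
    "BatchNorm1d",
    "Conv3d",
    "Sequential",
    "Adam",
]


class Param:
    """A learnable tensor plus its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    """Affine map with He-normal weight initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x if train else None
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class BatchNorm1d(Layer):
    """Batch normalization over feature vectors with running statistics."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        self._ivar = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._ivar
        self._train = train
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        xhat, ivar = self._xhat, self._ivar
        self.gamma.grad += (grad * xhat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        dxhat = grad * self.gamma.value
        if not self._train:
            return dxhat * ivar
        n = grad.shape[0]
        return (ivar / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )


def _im2col(x: np.ndarray, k: int, stride: int):
    """Unfold (B, C, D, H, W) into (B * n_out_voxels, C * k^3) columns.

    Column ordering is (channel, kz, ky, kx), matching
    ``W.reshape(c_out, c_in * k**3)``.
    """
    win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]
    b, c, d, h, w = win.shape[:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(b * d * h * w, c * k**3)
    return np.ascontiguousarray(cols), (d, h, w)


class Conv3d(Layer):
    """3D convolution (cross-correlation) via im2col.

    The input gradient is accumulated per kernel offset: for offset j,
    ``dx_padded[.., j + s*o] += g[.., o] @ W[:, :, j]`` — k³ small matrix
    products into strided views, which is far cheaper than materializing
    the transposed convolution explicitly.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 3,
        stride: int = 1,
        padding: int = 1,
        rng: np.random.Generator | None = None,
        needs_input_grad: bool = True,
    ):
        self.needs_input_grad = needs_input_grad
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel**3
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel, kernel)))
        self.b = Param(np.zeros(c_out))
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.pad = kernel, stride, padding

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        p = self.pad
        self._in_shape = x.shape
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        cols, (d, h, w) = _im2col(x, self.k, self.stride)
        self._cols = cols if train else None
        wmat = self.W.value.reshape(self.c_out, -1)
        out = cols @ wmat.T + self.b.value
        b = x.shape[0]
        return out.reshape(b, d, h, w, self.c_out).transpose(0, 4, 1, 2, 3)

    def backward(self, grad):
        b, co, do, ho, wo = grad.shape
        k, s, p = self.k, self.stride, self.pad
        gm = np.ascontiguousarray(grad.transpose(0, 2, 3, 4, 1)).reshape(-1, co)
        self.W.grad += (gm.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += gm.sum(axis=0)
        if not self.needs_input_grad:  # first layer: skip the costly dx pass
            return None

        _, _, din, hin, win = self._in_shape
        dp, hp, wp = din + 2 * p, hin + 2 * p, win + 2 * p
        full = np.zeros((b, self.c_in, dp, hp, wp), dtype=np.float32)
        for jz in range(k):
            for jy in range(k):
                for jx in range(k):
                    chunk = gm @ self.W.value[:, :, jz, jy, jx]  # (b*N, c_in)
                    chunk = chunk.reshape(b, do, ho, wo, self.c_in).transpose(0, 4, 1, 2, 3)
                    full[:, :, jz : jz + s * do : s, jy : jy + s * ho : s,
                         jx : jx + s * wo : s] += chunk
        return full[:, :, p : p + din, p : p + hin, p : p + win]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
            if grad is None:  # a layer that does not propagate an input grad
                break
        return grad


class Adam:
    """Adam with bias correction; ``lr`` may be reassigned between steps."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.99,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
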
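"""Minimal NumPy neural-network layers with analytic backpropagation.

All tensors use NCHW layout (batch, channels, height, width). Each layer
caches what its backward pass needs during ``forward(training=True)`` and
releases it after ``backward``. Convolutions use im2col so the heavy
lifting happens inside BLAS matrix products.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "MaxPool2d",
    "BatchNorm2d",
    "relu",
    "relu_backward",
    "softmax_channels",
    "Adam",
    "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    """Glorot/Xavier uniform initialisation."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Parameter:
    """A trainable array and its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)


class Module:
    """Base class: parameter bookkeeping shared by all layers."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0


class Conv2d(Module):
    """2-D convolution, stride 1, odd kernel, zero same-padding, with bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        if kernel_size % 2 != 1:
            raise ValueError(f"kernel_size must be odd, got {kernel_size}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        k = kernel_size
        fan_in = in_channels * k * k
        self.weight = Parameter(
            glorot_uniform(rng, (out_channels, in_channels, k, k), fan_in, out_channels * k * k, dtype),
            "conv.weight")
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype), "conv.bias")
        self._cache = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel_size
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        n, c, h, w = x.shape
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        cols = self._im2col(x)
        wmat = self.weight.value.reshape(self.out_channels, -1)
        out = cols @ wmat.T + self.bias.value
        out = out.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)
        if training:
            self._cache = (cols, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        self._cache = None
        n, c, h, w = x_shape
        k = self.kernel_size
        p = k // 2
        g = grad_out.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_channels)
        self.weight.grad += (g.T @ cols).reshape(self.weight.value.shape)
        self.bias.grad += g.sum(axis=0)
        wmat = self.weight.value.reshape(self.out_channels, -1)
        dcols = (g @ wmat).reshape(n, h, w, c, k, k)
        # col2im scatter-add back into the padded input gradient
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=grad_out.dtype)
        for a in range(k):
            for b in range(k):
                dxp[:, :, a:a + h, b:b + w] += dcols[:, :, :, :, a, b].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]


class ConvTranspose2d(Module):
    """Transpose convolution with kernel 2, stride 2 (exact 2x upsampling).

    Output blocks do not overlap, so each input pixel maps to one 2x2
    output patch.
    """

    kernel_size = 2
    stride = 2

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels
        self.weight = Parameter(
            glorot_uniform(rng, (in_channels, out_channels, 2, 2), fan_in * 4, out_channels * 4, dtype),
            "tconv.weight")
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype), "tconv.bias")
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        # out[n,d,2i+a,2j+b] = sum_c W[c,d,a,b] x[n,c,i,j] + bias[d]
        out = np.einsum("nchw,cdab->ndhawb", x, self.weight.value, optimize=True)
        out = out.reshape(n, self.out_channels, 2 * h, 2 * w)
        out += self.bias.value[None, :, None, None]
        if training:
            self._cache = x
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x = self._cache
        self._cache = None
        n, d, H, W = grad_out.shape
        g = grad_out.reshape(n, d, H // 2, 2, W // 2, 2)  # n d h a w b
        self.weight.grad += np.einsum("nchw,ndhawb->cdab", x, g, optimize=True)
        self.bias.grad += grad_out.sum(axis=(0, 2, 3))
        return np.einsum("ndhawb,cdab->nchw", g, self.weight.value, optimize=True)


class MaxPool2d(Module):
    """2x2 max pooling with stride 2."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if training:
            mask = xr == out[:, :, :, None, :, None]
            # break ties: keep only the first maximal element per window
            flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
            first = np.cumsum(flat, axis=-1) == 1
            flat &= first
            mask = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            self._cache = mask
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        mask = self._cache
        self._cache = None
        n, c, hh, ww = grad_out.shape
        g = mask * grad_out[:, :, :, None, :, None]
        return g.reshape(n, c, hh * 2, ww * 2)


class BatchNorm2d(Module):
    """Per-channel batch normalisation over (N, H, W).

    Training mode normalises with batch statistics and updates running
    estimates (momentum 0.1); inference mode uses the running estimates.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=dtype), "bn.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(self.running_var.dtype)
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        if training:
            self._cache = (xhat, inv_std)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        n, c, h, w = grad_out.shape
        m = n * h * w
        self.gamma.grad += (grad_out * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad_out.sum(axis=(0, 2, 3))
        g = grad_out * self.gamma.value[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3).reshape(1, c, 1, 1)
        gx = (g * xhat).sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
        dx = (g - gsum / m - xhat * gx / m) * inv_std[None, :, None, None]
        return dx


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(grad_out: np.ndarray, pre_activation: np.ndarray) -> np.ndarray:
    return grad_out * (pre_activation > 0)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the channel axis of NCHW logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam optimiser over a flat parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
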
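"""A compact convolutional-network engine on numpy.

Implements exactly the layer vocabulary the enhancement network needs —
4×4 convolutions and transposed convolutions with stride 2, batch-1
normalization, LeakyReLU/ReLU/tanh/sigmoid — with hand-written backward
passes and an Adam optimizer. Tensors are single samples shaped
``(channels, height, width)``; the training scheme is batch-size 1
throughout, so no batch axis is carried.

Every layer follows the same protocol: ``forward(x, train)`` caches what
backward needs, ``backward(dy)`` returns ``dx`` and accumulates parameter
gradients into ``Param.grad``. Gradients are verified against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "ChannelNorm",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "Sequential",
    "Adam",
]


class Param:
    """A learnable tensor with its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _init_conv(rng: np.random.Generator, shape: tuple[int, ...],
               dtype: np.dtype) -> np.ndarray:
    # N(0, 0.02) init, the DCGAN/Pix2Pix convention for 4x4 GAN convs.
    return (rng.standard_normal(shape) * 0.02).astype(dtype)


class Conv2d(Layer):
    """2D convolution, kernel k×k, stride s, symmetric zero padding p.

    The forward pass is decomposed over kernel offsets: for each (ki, kj)
    the strided input window contributes one (C_out × C_in) matmul, which
    keeps memory flat (no im2col buffer) and vectorizes well.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 dtype=np.float64) -> None:
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s, self.p = kernel, stride, pad
        self.weight = Param(_init_conv(rng, (out_ch, in_ch, kernel, kernel), dtype), "conv.w")
        self.bias = Param(np.zeros(out_ch, dtype=dtype), "conv.b")
        self._xp: np.ndarray | None = None
        self._in_shape: tuple[int, int] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def out_size(self, h: int, w: int) -> tuple[int, int]:
        return ((h + 2 * self.p - self.k) // self.s + 1,
                (w + 2 * self.p - self.k) // self.s + 1)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        ho, wo = self.out_size(h, w)
        if ho < 1 or wo < 1:
            raise ValueError(f"input {h}x{w} too small for k={self.k}, s={self.s}, p={self.p}")
        xp = np.pad(x, ((0, 0), (self.p, self.p), (self.p, self.p)))
        W = self.weight.data
        y = np.zeros((self.out_ch, ho, wo), dtype=x.dtype)
        for ki in range(self.k):
            for kj in range(self.k):
                xs = xp[:, ki:ki + self.s * ho:self.s, kj:kj + self.s * wo:self.s]
                y += np.tensordot(W[:, :, ki, kj], xs, axes=1)
        y += self.bias.data[:, None, None]
        self._xp, self._in_shape = xp, (h, w)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, (h, w) = self._xp, self._in_shape
        ho, wo = dy.shape[1:]
        W = self.weight.data
        dxp = np.zeros_like(xp)
        self.bias.grad += dy.sum(axis=(1, 2))
        for ki in range(self.k):
            for kj in range(self.k):
                xs = xp[:, ki:ki + self.s * ho:self.s, kj:kj + self.s * wo:self.s]
                self.weight.grad[:, :, ki, kj] += np.tensordot(dy, xs, axes=([1, 2], [1, 2]))
                dxp[:, ki:ki + self.s * ho:self.s, kj:kj + self.s * wo:self.s] += (
                    np.tensordot(W[:, :, ki, kj].T, dy, axes=1)
                )
        if self.p:
            return dxp[:, self.p:self.p + h, self.p:self.p + w]
        return dxp


class ConvTranspose2d(Layer):
    """2D transposed convolution (fractionally-strided), kernel k, stride s,
    output trimmed by padding p: output size = (H-1)*s - 2p + k."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 dtype=np.float64) -> None:
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s, self.p = kernel, stride, pad
        self.weight = Param(_init_conv(rng, (in_ch, out_ch, kernel, kernel), dtype), "convT.w")
        self.bias = Param(np.zeros(out_ch, dtype=dtype), "convT.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def out_size(self, h: int, w: int) -> tuple[int, int]:
        return ((h - 1) * self.s - 2 * self.p + self.k,
                (w - 1) * self.s - 2 * self.p + self.k)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        hf, wf = (h - 1) * self.s + self.k, (w - 1) * self.s + self.k
        W = self.weight.data
        yf = np.zeros((self.out_ch, hf, wf), dtype=x.dtype)
        for ki in range(self.k):
            for kj in range(self.k):
                yf[:, ki:ki + self.s * h:self.s, kj:kj + self.s * w:self.s] += (
                    np.tensordot(W[:, :, ki, kj].T, x, axes=1)
                )
        y = yf[:, self.p:hf - self.p, self.p:wf - self.p] if self.p else yf
        y = y + self.bias.data[:, None, None]
        self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        c, h, w = x.shape
        hf, wf = (h - 1) * self.s + self.k, (w - 1) * self.s + self.k
        dyf = np.zeros((self.out_ch, hf, wf), dtype=dy.dtype)
        if self.p:
            dyf[:, self.p:hf - self.p, self.p:wf - self.p] = dy
        else:
            dyf[:] = dy
        W = self.weight.data
        dx = np.zeros_like(x)
        self.bias.grad += dy.sum(axis=(1, 2))
        for ki in range(self.k):
            for kj in range(self.k):
                dyf_s = dyf[:, ki:ki + self.s * h:self.s, kj:kj + self.s * w:self.s]
                dx += np.tensordot(W[:, :, ki, kj], dyf_s, axes=1)
                self.weight.grad[:, :, ki, kj] += np.tensordot(x, dyf_s, axes=([1, 2], [1, 2]))
        return dx


class ChannelNorm(Layer):
    """Per-channel normalization over the spatial axes with learnable
    affine parameters.

    This is exactly what batch normalization computes at batch size 1
    (the training scheme here mandates batch 1): train-time statistics are
    the current sample's spatial mean/variance, and exponential running
    statistics are kept and frozen for inference, so a trained network is
    deterministic at apply time.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float64) -> None:
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels, dtype=dtype), "norm.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), "norm.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(1, 2))
            var = x.var(axis=(1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        y = self.gamma.data[:, None, None] * xhat + self.beta.data[:, None, None]
        self._cache = (xhat, inv_std, train)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, train = self._cache
        n = xhat.shape[1] * xhat.shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2))
        self.beta.grad += dy.sum(axis=(1, 2))
        dxhat = dy * self.gamma.data[:, None, None]
        if not train:
            return dxhat * inv_std[:, None, None]
        mean_dxhat = dxhat.mean(axis=(1, 2))[:, None, None]
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(1, 2))[:, None, None]
        return inv_std[:, None, None] * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class ReLU(LeakyReLU):
    def __init__(self) -> None:
        super().__init__(slope=0.0)


class Tanh(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam with the adversarial-training convention betas (0.5, 0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - b1) * (p.grad - m)
            v += (1.0 - b2) * (p.grad**2 - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for dst, src in zip(self.m, state["m"]):
            dst[...] = src
        for dst, src in zip(self.v, state["v"]):
            dst[...] = src
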
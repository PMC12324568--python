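"""Minimal CPU neural-network engine: strided valid convolutions, transposed
convolutions, batch normalisation, dense layers and Adam, with explicit
backpropagation.

Shapes follow the (batch, channel, height, width) convention. All layers cache
whatever the backward pass needs on ``forward`` and accumulate parameter
gradients into ``Param.grad``; ``zero_grad`` resets them. float32 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "LeakyReLU",
    "Dense",
    "Sequential",
    "Adam",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x, dtype=np.float32)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Layer):
    """Valid (no padding) 2-D convolution, implemented via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.W = Param(_he_init(rng, c_in * k * k, (c_out, c_in * k * k)))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    @staticmethod
    def out_size(s: int, k: int = 3, stride: int = 2) -> int:
        return (s - k) // stride + 1

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, s = self.k, self.stride
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]                       # (B, C, Ho, Wo, k, k)
        b, c, ho, wo = win.shape[:4]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * k * k)
        return np.ascontiguousarray(cols), ho, wo

    def forward(self, x, train=True):
        x = np.asarray(x, dtype=np.float32)
        cols, ho, wo = self._im2col(x)
        y = cols @ self.W.value.T + self.b.value
        self._cache = (cols, x.shape, ho, wo)
        return y.transpose(0, 2, 1).reshape(x.shape[0], self.c_out, ho, wo)

    def backward(self, grad):
        cols, x_shape, ho, wo = self._cache
        b = x_shape[0]
        g2 = grad.reshape(b, self.c_out, ho * wo).transpose(0, 2, 1)  # (B, P, c_out)
        self.W.grad += np.einsum("bpc,bpk->ck", g2, cols, optimize=True)
        self.b.grad += g2.sum(axis=(0, 1))
        gcols = (g2 @ self.W.value).reshape(b, ho, wo, self.c_in, self.k, self.k)
        gx = np.zeros(x_shape, dtype=np.float32)
        s = self.stride
        for ki in range(self.k):
            for kj in range(self.k):
                gx[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += \
                    gcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return gx


class ConvTranspose2d(Layer):
    """Stride-2 transposed convolution (mirror of Conv2d), with optional
    output padding to reproduce an exact encoder size chain."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 2,
                 output_padding: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.stride, self.output_padding = stride, output_padding
        self.W = Param(_he_init(rng, c_in, (c_in, c_out * k * k)))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def out_size(self, s: int) -> int:
        return (s - 1) * self.stride + self.k + self.output_padding

    def forward(self, x, train=True):
        x = np.asarray(x, dtype=np.float32)
        b, c, hi, wi = x.shape
        k, s = self.k, self.stride
        xr = x.transpose(0, 2, 3, 1).reshape(b, hi * wi, c)
        cols = (xr @ self.W.value).reshape(b, hi, wi, self.c_out, k, k)
        ho, wo = self.out_size(hi), self.out_size(wi)
        y = np.zeros((b, self.c_out, ho, wo), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                y[:, :, ki:ki + s * hi:s, kj:kj + s * wi:s] += \
                    cols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        y += self.b.value[None, :, None, None]
        self._cache = (xr, (b, c, hi, wi))
        return y

    def backward(self, grad):
        xr, (b, c, hi, wi) = self._cache
        k, s = self.k, self.stride
        gcols = np.empty((b, hi, wi, self.c_out, k, k), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                gcols[:, :, :, :, ki, kj] = \
                    grad[:, :, ki:ki + s * hi:s, kj:kj + s * wi:s].transpose(0, 2, 3, 1)
        gflat = gcols.reshape(b, hi * wi, self.c_out * k * k)
        self.W.grad += np.einsum("bpc,bpf->cf", xr, gflat, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        gx = (gflat @ self.W.value.T).reshape(b, hi, wi, c).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(gx)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd, x.shape, train)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, invstd, shape, train = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return grad * g * invstd[None, :, None, None]
        n = shape[0] * shape[2] * shape[3]
        gxhat = grad * g
        mean_g = gxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_gx = (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return invstd[None, :, None, None] * (gxhat - mean_g - xhat * mean_gx)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1):
        self.slope = slope
        self._mask = None

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(_he_init(rng, n_in, (n_in, n_out)))
        self.b = Param(np.zeros(n_out, dtype=np.float32))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Adam:
    """Adam with optional L2 weight decay added to the raw gradient."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
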
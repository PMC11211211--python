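"""Minimal 1-D convolutional network primitives in NumPy.

Implements exactly the layers the dual-branch residual classifier needs --
Conv1d (im2col + GEMM), BatchNorm1d, ReLU, MaxPool1d, global average
pooling, Linear -- each with a hand-written backward pass, plus Adam and a
numerically stable sigmoid/binary-cross-entropy head.  Everything is
float32 and fully deterministic given the initializing generator.

Layers follow a simple protocol: ``forward(x, train)`` caches what backward
needs; ``backward(grad)`` returns the input gradient and accumulates
parameter gradients in ``Param.grad``.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _same_pad(w: int, k: int, stride: int) -> tuple[int, int]:
    """Left/right padding so that out = ceil(w / stride)."""
    out = -(-w // stride)
    total = max((out - 1) * stride + k - w, 0)
    return total // 2, total - total // 2


class Conv1d(Layer):
    """1-D convolution with 'same' padding, arbitrary stride."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1, *,
                 rng: np.random.Generator):
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        fan_in = in_ch * kernel
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, fan_in)))
        self.bias = Param(np.zeros(out_ch))
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, w = x.shape
        pl, pr = _same_pad(w, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        # windows: (n, c, w_out, k)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        win = win[:, :, :: self.stride, :]
        w_out = win.shape[2]
        cols = win.transpose(0, 2, 1, 3).reshape(n * w_out, c * self.kernel)
        y = cols @ self.weight.value.T + self.bias.value
        if train:
            self._cache = (cols, (n, c, w, pl, pr, w_out))
        return np.ascontiguousarray(y.reshape(n, w_out, self.out_ch).transpose(0, 2, 1))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, (n, c, w, pl, pr, w_out) = self._cache
        g = grad.transpose(0, 2, 1).reshape(n * w_out, self.out_ch)
        self.weight.grad += g.T @ cols
        self.bias.grad += g.sum(axis=0)
        dcols = (g @ self.weight.value).reshape(n, w_out, c, self.kernel)
        dxp = np.zeros((n, c, w + pl + pr), dtype=F32)
        starts = np.arange(w_out) * self.stride
        for j in range(self.kernel):
            np.add.at(dxp, (slice(None), slice(None), starts + j),
                      dcols[:, :, :, j].transpose(0, 2, 1))
        return dxp[:, :, pl : pl + w]


class BatchNorm1d(Layer):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = grad.shape[0] * grad.shape[2]  # reduction size per channel
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        gh = grad * self.gamma.value[None, :, None]
        term = (
            gh
            - gh.mean(axis=(0, 2), keepdims=True)
            - xhat * (gh * xhat).sum(axis=(0, 2), keepdims=True) / m
        )
        return term * inv[None, :, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling (kernel == stride); trailing remainder is
    dropped, but never below an output length of 1."""

    def __init__(self, kernel: int = 2):
        self.kernel = kernel

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, w = x.shape
        if w < self.kernel:  # protect very short inputs: identity
            if train:
                self._cache = None
            return x
        w_out = w // self.kernel
        xr = x[:, :, : w_out * self.kernel].reshape(n, c, w_out, self.kernel)
        idx = xr.argmax(axis=3)
        if train:
            self._cache = (idx, (n, c, w, w_out))
        return xr.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cache is None:
            return grad
        idx, (n, c, w, w_out) = self._cache
        dx = np.zeros((n, c, w_out, self.kernel), dtype=F32)
        np.put_along_axis(dx, idx[..., None], grad[..., None], axis=3)
        out = np.zeros((n, c, w), dtype=F32)
        out[:, :, : w_out * self.kernel] = dx.reshape(n, c, w_out * self.kernel)
        return out


class GlobalAvgPool1d(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._w = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, :, None], self._w, axis=2) / self._w


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, *, rng: np.random.Generator):
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / in_f), (out_f, in_f)))
        self.bias = Param(np.zeros(out_f))

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    x = logits.astype(np.float64)
    y = targets.astype(np.float64)
    # log(1 + e^x) computed stably
    loss = float(np.mean(np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x)))))
    grad = ((sigmoid(x) - y) / x.size).astype(F32)
    return loss, grad


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
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
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
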
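"""Minimal CPU neural-network engine (numpy) for the spectrogram classifiers.

Implements exactly the layer vocabulary the two CNN architectures need —
strided 2-D convolution (im2col/col2im over BLAS matmul), batch
normalization, ReLU, inverted dropout, max pooling, adaptive (global)
average pooling and a linear head — together with softmax cross-entropy and
SGD with classical momentum. Every source of randomness (weight init,
dropout masks) comes from explicitly seeded generators, so training runs are
bit-reproducible.

Layers follow an explicit forward/backward protocol: ``forward(x)`` caches
what ``backward(grad)`` needs; ``backward`` accumulates parameter gradients
and returns the input gradient.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Module:
    training: bool = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for v in vars(self).values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def num_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def _out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


class Conv2d(Module):
    """2-D convolution (cross-correlation) via im2col, He-normal init."""

    def __init__(
        self, in_channels: int, out_channels: int, kernel: int = 3,
        stride: int = 1, padding: int = 0, rng: np.random.Generator | None = None,
        bias: bool = True,
    ) -> None:
        rng = rng or np.random.default_rng()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.stride, self.padding = kernel, stride, padding
        fan_in = in_channels * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self._cache: tuple | None = None

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        k, s = self.kernel, self.stride
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s][:, :, :ho, :wo]  # (B, C, ho, wo, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(-1, self.in_channels * k * k)
        return np.ascontiguousarray(cols, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        ho, wo = _out_size(h, k, s, p), _out_size(w, k, s, p)
        if ho < 1 or wo < 1:
            raise ValueError(f"input {h}x{w} too small for kernel {k}, stride {s}, padding {p}")
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = self._im2col(xp, ho, wo)
        wmat = self.weight.value.reshape(self.out_channels, -1).T
        out = cols @ wmat
        if self.bias is not None:
            out += self.bias.value
        out = out.reshape(b, ho, wo, self.out_channels).transpose(0, 3, 1, 2)
        self._cache = (cols, x.shape, ho, wo)
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, x_shape, ho, wo = self._cache
        b, c, h, w = x_shape
        k, s, p = self.kernel, self.stride, self.padding
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.out_channels)
        self.weight.grad += (cols.T @ g).T.reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=0)
        dcols = g @ self.weight.value.reshape(self.out_channels, -1)
        dcols = dcols.reshape(b, ho, wo, c, k, k)
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps, self.momentum = eps, momentum
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes = (0, 2, 3)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = self.gamma.value[None, :, None, None]
        if not self.training:
            return (grad * g * inv[None, :, None, None]).astype(np.float32)
        dxhat = grad * g
        dx = (inv[None, :, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True)
        )
        return dx.astype(np.float32)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0).astype(np.float32)


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator | None = None) -> None:
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return (grad * self._mask).astype(np.float32)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0) -> None:
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x
        ho, wo = _out_size(h, k, s, p), _out_size(w, k, s, p)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s][:, :, :ho, :wo].reshape(b, c, ho, wo, k * k)
        self._argmax = win.argmax(axis=-1)
        self._shapes = (x.shape, xp.shape, ho, wo)
        return win.max(axis=-1).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, xp_shape, ho, wo = self._shapes
        b, c, h, w = x_shape
        k, s, p = self.kernel, self.stride, self.padding
        dxp = np.zeros(xp_shape, dtype=np.float32)
        bi, ci, hi, wi = np.meshgrid(
            np.arange(b), np.arange(c), np.arange(ho), np.arange(wo), indexing="ij"
        )
        ki, kj = np.divmod(self._argmax, k)
        np.add.at(dxp, (bi, ci, hi * s + ki, wi * s + kj), grad)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class AdaptiveAvgPool(Module):
    """Global average pooling to 1x1 per channel, flattened to (B, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3)).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self._shape).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_features))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return (x @ self.weight.value + self.bias.value).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return (grad @ self.weight.value.T).astype(np.float32)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = logits.shape[0]
    loss = -float(logp[np.arange(n), labels].mean())
    probs = np.exp(logp)
    grad = probs
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


class SGD:
    """Stochastic gradient descent with classical momentum: v ← μv + g; p ← p − ηv."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.0) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 <= momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        self.params = params
        self.lr, self.momentum = lr, momentum
        self.velocity = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v += p.grad
            p.value -= self.lr * v
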
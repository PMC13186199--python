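"""Minimal feed-forward neural-network layers on NumPy.

The trainable head of the predictor is small (two 2-layer MLP encoders, an
element-wise fusion, and a shallow 1-D convolutional decoder), so forward and
backward passes are written explicitly per layer rather than through an
autodiff framework.  Every layer caches what its backward pass needs during
``forward(..., train=True)``; gradients accumulate into ``Parameter.grad``.

All backward passes are covered by numerical gradient checks in the test
suite.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base class: a layer exposes trainable parameters and optional state."""

    def parameters(self) -> list[Parameter]:
        return []

    def state(self) -> list[np.ndarray]:
        """Non-trainable arrays that must persist in checkpoints
        (batch-norm running statistics)."""
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = Parameter(xavier_uniform(rng, in_dim, out_dim,
                                          (in_dim, out_dim)))
        self.b = Parameter(np.zeros(out_dim))
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


def hswish(x: np.ndarray) -> np.ndarray:
    """H-swish activation: x * min(max(x + 3, 0), 6) / 6.

    Saturates to 0 below -3 and to the identity above +3.
    """
    x = np.asarray(x, dtype=float)
    return x * np.clip(x + 3.0, 0.0, 6.0) / 6.0


def relu6(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 6.0)


class HSwish(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return hswish(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        # piecewise derivative: 0 below -3, (2x+3)/6 in between, 1 above 3
        d = np.where(x <= -3.0, 0.0,
                     np.where(x >= 3.0, 1.0, (2.0 * x + 3.0) / 6.0))
        return grad * d


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class BatchNorm(Layer):
    """Batch normalisation over all axes except axis 1 (the channel axis).

    Works both on (batch, features) activations and (batch, channels, length)
    convolutional maps.  Training uses batch statistics and updates running
    estimates with the given momentum; evaluation uses the running estimates
    and raises if none have been accumulated yet.
    """

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self._initialized = np.zeros(1)  # persisted flag

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def state(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var, self._initialized]

    def _bshape(self, ndim: int) -> tuple[int, ...]:
        shape = [1] * ndim
        shape[1] = -1
        return tuple(shape)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(i for i in range(x.ndim) if i != 1)
        bs = self._bshape(x.ndim)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mean
            self.running_var[...] = (1 - m) * self.running_var + m * var
            self._initialized[0] = 1.0
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(bs)) * inv_std.reshape(bs)
            self._xhat, self._inv_std, self._axes = xhat, inv_std, axes
        else:
            if not self._initialized[0]:
                raise RuntimeError(
                    "batch-norm evaluated before any training step: no "
                    "running statistics available"
                )
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean.reshape(bs)) * inv_std.reshape(bs)
        return self.gamma.value.reshape(bs) * xhat + self.beta.value.reshape(bs)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes = self._xhat, self._inv_std, self._axes
        bs = self._bshape(grad.ndim)
        n = np.prod([grad.shape[i] for i in axes])
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self.gamma.value.reshape(bs)
        sum_dxhat = dxhat.sum(axis=axes).reshape(bs)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=axes).reshape(bs)
        return (inv_std.reshape(bs) / n) * (
            n * dxhat - sum_dxhat - xhat * sum_dxhat_xhat
        )


class Conv1d(Layer):
    """1-D convolution (stride 1) via im2col."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int, rng: np.random.Generator):
        fan_in = in_channels * kernel_size
        self.W = Parameter(xavier_uniform(
            rng, fan_in, out_channels, (out_channels, fan_in)))
        self.b = Parameter(np.zeros(out_channels))
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.kernel_size, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        l_out = xp.shape[2] - k + 1
        # (B, C, L_out, k) -> (B, L_out, C*k)
        cols = np.stack([xp[:, :, j:j + l_out] for j in range(k)], axis=-1)
        return cols.transpose(0, 2, 1, 3).reshape(x.shape[0], l_out, -1)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols = self._im2col(x)
        if train:
            self._cols, self._in_len = cols, x.shape[2]
        y = cols @ self.W.value.T + self.b.value
        return y.transpose(0, 2, 1)  # (B, out_channels, L_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, p = self.kernel_size, self.padding
        g = grad.transpose(0, 2, 1)  # (B, L_out, out)
        b_size, l_out, _ = g.shape
        self.W.grad += np.einsum("blo,blf->of", g, self._cols)
        self.b.grad += g.sum(axis=(0, 1))
        dcols = g @ self.W.value  # (B, L_out, C*k)
        dcols = dcols.reshape(b_size, l_out, self.in_channels, k)
        dcols = dcols.transpose(0, 2, 1, 3)  # (B, C, L_out, k)
        dxp = np.zeros((b_size, self.in_channels, self._in_len + 2 * p))
        for j in range(k):
            dxp[:, :, j:j + l_out] += dcols[:, :, :, j]
        return dxp[:, :, p:self._in_len + p] if p else dxp


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def state(self) -> list[np.ndarray]:
        return [s for layer in self.layers for s in layer.state()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
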
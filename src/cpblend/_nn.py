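"""Minimal NumPy neural-network layers with reverse-mode gradients.

Just enough machinery for a small DCGAN at 32 x 32: dense, 3x3 convolution
(stride 1 or 2), nearest-neighbour 2x up-sampling, batch normalization,
dropout, ReLU/tanh/sigmoid, Adam, and binary cross-entropy.  All state is
NumPy; a run is deterministic given the seeds that feed the weight-init and
training generators.

Layers cache their last forward activations, so the usage pattern is
forward -> backward on the same batch.  Gradients accumulate across
backward calls until ``zero_grad``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    kind = "layer"

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(param, grad) pairs; arrays are updated in place."""
        return []

    def zero_grad(self) -> None:
        for _, g in self.parameters():
            g[...] = 0.0


class Dense(Layer):
    kind = "dense"

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, 0.02, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw += self._x.T @ grad
        self.gb += grad.sum(axis=0)
        return grad @ self.w.T

    def parameters(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class Reshape(Layer):
    kind = "reshape"

    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape

    def forward(self, x, training):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Flatten(Layer):
    kind = "flatten"

    def forward(self, x, training):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Conv2d(Layer):
    """3x3 convolution, padding 1, stride 1 or 2, NCHW layout."""

    kind = "conv"

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        stride: int = 1,
        kernel: int = 3,
    ):
        self.stride = stride
        self.k = kernel
        self.pad = kernel // 2
        self.w = rng.normal(0.0, 0.02, size=(c_out, c_in, kernel, kernel))
        self.b = np.zeros(c_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, training):
        p, s, k = self.pad, self.stride, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        self._win = win
        self._x_shape = x.shape
        return np.einsum("nchwij,ocij->nohw", win, self.w) + self.b[None, :, None, None]

    def backward(self, grad):
        p, s, k = self.pad, self.stride, self.k
        n, c, h, w = self._x_shape
        ho, wo = grad.shape[2], grad.shape[3]
        self.gw += np.einsum("nchwij,nohw->ocij", self._win, grad)
        self.gb += grad.sum(axis=(0, 2, 3))
        dcols = np.einsum("nohw,ocij->nchwij", grad, self.w)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ]
        return dxp[:, :, p : p + h, p : p + w]

    def parameters(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class UpsampleNearest2x(Layer):
    kind = "upsample"

    def forward(self, x, training):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        n, c, h2, w2 = grad.shape
        return grad.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class BatchNorm2d(Layer):
    kind = "batchnorm"

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._xhat, self._std, self._training = xhat, std, training
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        axes = (0, 2, 3)
        xhat, std = self._xhat, self._std
        self.ggamma += (grad * xhat).sum(axis=axes)
        self.gbeta += grad.sum(axis=axes)
        dxhat = grad * self.gamma[None, :, None, None]
        if not self._training:
            return dxhat / std[None, :, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        mean_dxhat = dxhat.sum(axis=axes) / m
        mean_dxhat_xhat = (dxhat * xhat).sum(axis=axes) / m
        return (
            dxhat
            - mean_dxhat[None, :, None, None]
            - xhat * mean_dxhat_xhat[None, :, None, None]
        ) / std[None, :, None, None]

    def parameters(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]


class ReLU(Layer):
    kind = "relu"

    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Tanh(Layer):
    kind = "tanh"

    def forward(self, x, training):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)


class Sigmoid(Layer):
    kind = "sigmoid"

    def forward(self, x, training):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Dropout(Layer):
    kind = "dropout"

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout p must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x, training):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def describe(self) -> list[str]:
        """Ordered layer-kind names (the architecture descriptor)."""
        return [layer.kind for layer in self.layers]

    def state_arrays(self) -> list[np.ndarray]:
        """All persistent arrays (weights + batch-norm running stats)."""
        arrays = []
        for layer in self.layers:
            for p, _ in layer.parameters():
                arrays.append(p)
            if isinstance(layer, BatchNorm2d):
                arrays.extend([layer.running_mean, layer.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        targets = self.state_arrays()
        if len(targets) != len(arrays):
            raise ValueError(
                f"state mismatch: expected {len(targets)} arrays, got {len(arrays)}"
            )
        for dst, src in zip(targets, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch: {dst.shape} vs {src.shape}")
            dst[...] = src


class Adam:
    def __init__(
        self,
        params: list[tuple[np.ndarray, np.ndarray]],
        lr: float = 2e-4,
        beta1: float = 0.5,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_loss(p: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Binary cross-entropy against a constant target; returns (loss, dL/dp)."""
    p = np.clip(p, 1e-7, 1.0 - 1e-7)
    y = target
    loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    grad = (p - y) / (p * (1 - p)) / p.size
    return loss, grad
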
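"""Minimal feed-forward / convolutional / recurrent NN core on numpy.

Provides exactly the pieces the inversion and fusion models need: linear
layers, batch normalization, ReLU, dropout, a 1-D convolution, global
average pooling, a simple tanh recurrence, mean-squared-error loss and Adam.
All randomness flows through an explicit numpy Generator, so training is
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Linear",
    "BatchNorm1d",
    "ReLU",
    "Dropout",
    "Sequential",
    "Conv1d",
    "GlobalAvgPool1d",
    "SimpleRNN",
    "Adam",
    "mse_loss",
]


class Layer:
    def params(self):  # list of (value, grad) pairs
        return []

    def forward(self, x, train: bool):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)  # He initialization for ReLU stacks
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class BatchNorm1d(Layer):
    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.dgamma = np.zeros(n)
        self.dbeta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        n = grad.shape[0]
        self.dgamma[...] = (grad * self._xhat).sum(axis=0)
        self.dbeta[...] = grad.sum(axis=0)
        gx = grad * self.gamma
        return self._istd * (
            gx - gx.mean(axis=0) - self._xhat * (gx * self._xhat).mean(axis=0)
        ) if n > 1 else gx * self._istd


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Conv1d(Layer):
    """1-D convolution on (batch, channels, length) with stride, valid padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, kernel))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.stride = stride
        self.kernel = kernel

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train):
        L = x.shape[2]
        L_out = (L - self.kernel) // self.stride + 1
        idx = np.arange(L_out)[:, None] * self.stride + np.arange(self.kernel)
        self._idx, self._x = idx, x
        cols = x[:, :, idx]  # (B, C_in, L_out, K)
        self._cols = cols
        y = np.einsum("bclk,ock->bol", cols, self.W, optimize=True)
        return y + self.b[None, :, None]

    def backward(self, grad):
        self.dW[...] = np.einsum("bol,bclk->ock", grad, self._cols, optimize=True)
        self.db[...] = grad.sum(axis=(0, 2))
        dcols = np.einsum("bol,ock->bclk", grad, self.W, optimize=True)
        dx = np.zeros_like(self._x)
        np.add.at(dx, (slice(None), slice(None), self._idx), dcols)
        return dx


class GlobalAvgPool1d(Layer):
    """(batch, channels, length) -> (batch, channels)."""

    def forward(self, x, train):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._L, axis=2) / self._L


class SimpleRNN(Layer):
    """tanh recurrence over (batch, time, features); returns the last state."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.Wx = rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_in, n_hidden))
        self.Wh = rng.normal(0.0, np.sqrt(1.0 / n_hidden), size=(n_hidden, n_hidden))
        self.b = np.zeros(n_hidden)
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.Wx, self.dWx), (self.Wh, self.dWh), (self.b, self.db)]

    def forward(self, x, train):
        B, T, _ = x.shape
        h = np.zeros((B, self.Wh.shape[0]))
        self._x, self._hs = x, [h]
        for t in range(T):
            h = np.tanh(x[:, t] @ self.Wx + h @ self.Wh + self.b)
            self._hs.append(h)
        return h

    def backward(self, grad):
        x, hs = self._x, self._hs
        T = x.shape[1]
        self.dWx[...] = 0
        self.dWh[...] = 0
        self.db[...] = 0
        dx = np.zeros_like(x)
        dh = grad
        for t in range(T - 1, -1, -1):
            da = dh * (1.0 - hs[t + 1] ** 2)
            self.dWx += x[:, t].T @ da
            self.dWh += hs[t].T @ da
            self.db += da.sum(axis=0)
            dx[:, t] = da @ self.Wx.T
            dh = da @ self.Wh.T
        return dx


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay:
                p -= self.lr * self.weight_decay * p  # decoupled shrinkage


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size
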
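"""Minimal CPU neural-network layers (NHWC layout, float32).

Small, explicit forward/backward implementations sized for desk-scale
training runs: convolutions are expressed as im2col + matmul so the heavy
lifting stays inside BLAS. Each layer instance caches what its backward
pass needs from the most recent forward call.
"""
from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Conv2D:
    """Same-padded stride-1 convolution, k x k kernel.

    Computed as a sum of k*k shifted matmuls (one per kernel tap), which
    keeps peak memory low and stays inside BLAS.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, *, rng: np.random.Generator):
        fan_in = k * k * cin
        self.k = k
        self.cin, self.cout = cin, cout
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, cout)))
        self.b = Param(np.zeros(cout))
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        n, h, w, c = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        if train:
            self._xp = xp
            self._shape = x.shape
        Wt = self.W.value.reshape(k, k, c, self.cout)
        y = np.empty((n * h * w, self.cout), dtype=np.float32)
        y[:] = self.b.value
        for i in range(k):
            for j in range(k):
                xs = xp[:, i:i + h, j:j + w, :].reshape(-1, c)
                y += xs @ Wt[i, j]
        return y.reshape(n, h, w, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        k, p = self.k, self.k // 2
        dyf = np.ascontiguousarray(dy, dtype=np.float32).reshape(-1, self.cout)
        self.b.grad += dyf.sum(axis=0)
        Wt = self.W.value.reshape(k, k, c, self.cout)
        dW = self.W.grad.reshape(k, k, c, self.cout)
        dxp = np.zeros_like(self._xp)
        for i in range(k):
            for j in range(k):
                xs = self._xp[:, i:i + h, j:j + w, :].reshape(-1, c)
                dW[i, j] += xs.T @ dyf
                dxp[:, i:i + h, j:j + w, :] += (dyf @ Wt[i, j].T).reshape(n, h, w, c)
        self._xp = None
        if p:
            return dxp[:, p:-p, p:-p, :]
        return dxp


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; input H, W must be even."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        if train:
            self._mask = xr == y[:, :, None, :, None, :]
            self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dxr = self._mask * dy[:, :, None, :, None, :]
        return dxr.reshape(n, h, w, c)


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Dense:
    def __init__(self, fin: int, fout: int, *, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fin), (fin, fout)))
        self.b = Param(np.zeros(fout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class BatchNorm1D:
    """Batch normalisation over feature vectors (N, F)."""

    def __init__(self, f: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(f))
        self.beta = Param(np.zeros(f))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(f, dtype=np.float32)
        self.running_var = np.ones(f, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._xhat = (x - mu) / np.sqrt(var + self.eps)
            self._istd = 1.0 / np.sqrt(var + self.eps)
            return self.gamma.value * self._xhat + self.beta.value
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n = dy.shape[0]
        xhat, istd = self._xhat, self._istd
        self.gamma.grad += (dy * xhat).sum(axis=0)
        self.beta.grad += dy.sum(axis=0)
        dxhat = dy * self.gamma.value
        return istd / n * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))


class Dropout:
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over all leading dims; labels are integer class IDs.

    Returns (loss, dlogits). dlogits is already divided by the number of
    scored elements.
    """
    k = logits.shape[-1]
    p = softmax(logits)
    flat_p = p.reshape(-1, k)
    flat_l = labels.reshape(-1)
    n = flat_l.size
    eps = 1e-12
    loss = -np.log(flat_p[np.arange(n), flat_l] + eps).mean()
    d = flat_p.copy()
    d[np.arange(n), flat_l] -= 1.0
    return float(loss), (d / n).reshape(logits.shape).astype(np.float32)
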
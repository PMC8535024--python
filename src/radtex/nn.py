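"""Minimal CPU neural-network core (float32, numpy, channels-last).

Implements exactly the pieces the compact GLCM classifier needs: 3x3 'same'
convolution (im2col/GEMM), batch normalization, ReLU, 2x2 max pooling, fully
connected layers, class-weighted softmax cross-entropy, and Adam.

Activations are stored channels-last, ``(N, H, W, C)``, so the im2col gather
reduces to nine contiguous slice copies and both convolution passes run as
single BLAS GEMMs. Layers cache their forward inputs, so a ``forward`` must
precede each ``backward``. All randomness flows through an explicit
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Flatten",
    "Linear",
    "Sequential",
    "Adam",
    "softmax",
    "weighted_cross_entropy",
]

_F32 = np.float32


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    # kaiming-uniform with bound sqrt(1/fan_in), the common conv-net default
    bound = np.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(_F32)


@njit(cache=True, fastmath=True)
def _im2col3_kernel(xp: np.ndarray, h: int, w: int, c: int) -> np.ndarray:
    n = xp.shape[0]
    cols = np.empty((n * h * w, 9 * c), dtype=np.float32)
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                row = (ni * h + i) * w + j
                col = 0
                for a in range(3):
                    for b in range(3):
                        for ch in range(c):
                            cols[row, col] = xp[ni, i + a, j + b, ch]
                            col += 1
    return cols


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, 9*C) patch matrix for a 3x3 'same' window.

    Row layout is kernel-position-major: columns [k*C:(k+1)*C] hold the
    channels of the k-th window offset, k = ky*3 + kx.
    """
    n, h, w, c = x.shape
    xp = np.zeros((n, h + 2, w + 2, c), dtype=_F32)
    xp[:, 1:-1, 1:-1, :] = x
    return _im2col3_kernel(xp, h, w, c)


@njit(cache=True, fastmath=True)
def _bn_stats(x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean and biased variance of an (M, C) float32 view."""
    m, c = x2.shape
    mean = np.zeros(c, dtype=np.float64)
    sq = np.zeros(c, dtype=np.float64)
    for i in range(m):
        for j in range(c):
            v = np.float64(x2[i, j])
            mean[j] += v
            sq[j] += v * v
    mean /= m
    var = sq / m - mean * mean
    return mean.astype(np.float32), np.maximum(var, 0.0).astype(np.float32)


@njit(cache=True, fastmath=True)
def _bn_normalize(x2, mean, inv_std, gamma, beta):
    m, c = x2.shape
    xhat = np.empty_like(x2)
    out = np.empty_like(x2)
    for i in range(m):
        for j in range(c):
            z = (x2[i, j] - mean[j]) * inv_std[j]
            xhat[i, j] = z
            out[i, j] = gamma[j] * z + beta[j]
    return xhat, out


@njit(cache=True, fastmath=True)
def _bn_backward(dy2, xhat2, inv_std, gamma):
    m, c = dy2.shape
    dgamma = np.zeros(c, dtype=np.float64)
    dbeta = np.zeros(c, dtype=np.float64)
    for i in range(m):
        for j in range(c):
            dgamma[j] += np.float64(dy2[i, j]) * np.float64(xhat2[i, j])
            dbeta[j] += np.float64(dy2[i, j])
    dx = np.empty_like(dy2)
    for i in range(m):
        for j in range(c):
            dxhat = dy2[i, j] * gamma[j]
            dx[i, j] = (dxhat - np.float32(dbeta[j] * gamma[j] / m)
                        - xhat2[i, j] * np.float32(dgamma[j] * gamma[j] / m)) * inv_std[j]
    return dx, dgamma.astype(np.float32), dbeta.astype(np.float32)


@njit(cache=True)
def _pool_backward(x, out, dy):
    n, h, w, c = x.shape
    dx = np.zeros_like(x)
    for ni in range(n):
        for i in range(h // 2):
            for j in range(w // 2):
                for ch in range(c):
                    g = dy[ni, i, j, ch]
                    if g == 0.0:
                        continue
                    top = out[ni, i, j, ch]
                    # first matching window position takes the gradient
                    done = False
                    for a in range(2):
                        for b in range(2):
                            if x[ni, 2 * i + a, 2 * j + b, ch] == top:
                                dx[ni, 2 * i + a, 2 * j + b, ch] = g
                                done = True
                                break
                        if done:
                            break
    return dx


@njit(cache=True, fastmath=True)
def _adam_kernel(val, grad, m, v, b1, b2, scale, eps):
    for i in range(val.size):
        m[i] = b1 * m[i] + (np.float32(1.0) - b1) * grad[i]
        v[i] = b2 * v[i] + (np.float32(1.0) - b2) * grad[i] * grad[i]
        val[i] -= scale * m[i] / (np.sqrt(v[i]) + eps)


class Layer:
    """Base layer: parameters exposed as (name, value, grad) triples."""

    train_mode = True

    def params(self):
        return []

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 convolution, stride 1, zero padding 1 ('same')."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.cin, self.cout = in_channels, out_channels
        fan_in = in_channels * 9
        self.W = _kaiming_uniform(rng, (9 * in_channels, out_channels), fan_in)
        self.b = _kaiming_uniform(rng, (out_channels,), fan_in)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x):
        n, h, w, c = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        self._shape = (n, h, w)
        self._cols = _im2col3(x)
        out = self._cols @ self.W + self.b
        return out.reshape(n, h, w, self.cout)

    def backward(self, dy, need_input_grad: bool = True):
        n, h, w = self._shape
        dyf = dy.reshape(n * h * w, self.cout)
        self.dW[...] = self._cols.T @ dyf
        self.db[...] = dyf.sum(axis=0)
        if not need_input_grad:
            return None
        # dx = correlation of dy with spatially flipped kernels, in/out swapped
        wk = self.W.reshape(3, 3, self.cin, self.cout)
        w_back = wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(9 * self.cout, self.cin)
        w_back = np.ascontiguousarray(w_back)
        dx = _im2col3(dy.reshape(n, h, w, self.cout)) @ w_back
        return dx.reshape(n, h, w, self.cin)


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W) with running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=_F32)
        self.beta = np.zeros(channels, dtype=_F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def forward(self, x):
        shape = x.shape
        x2 = np.ascontiguousarray(x, dtype=_F32).reshape(-1, shape[-1])
        if self.train_mode:
            mean, var = _bn_stats(x2)
            m = x2.shape[0]
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(_F32)
            unbiased = var * m / max(m - 1, 1)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var.astype(np.float64) + self.eps)).astype(_F32)
        xhat2, out2 = _bn_normalize(x2, mean, inv_std, self.gamma, self.beta)
        self._cache = (xhat2, inv_std, shape)
        return out2.reshape(shape)

    def backward(self, dy):
        xhat2, inv_std, shape = self._cache
        dy2 = np.ascontiguousarray(dy, dtype=_F32).reshape(-1, shape[-1])
        if not self.train_mode:
            self.dgamma[...] = (dy2 * xhat2).sum(axis=0)
            self.dbeta[...] = dy2.sum(axis=0)
            return (dy2 * (self.gamma * inv_std)).reshape(shape)
        dx2, dgamma, dbeta = _bn_backward(dy2, xhat2, inv_std, self.gamma)
        self.dgamma[...] = dgamma
        self.dbeta[...] = dbeta
        return dx2.reshape(shape)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; even spatial dims required.

    Gradient for tied maxima is routed to the first window position in
    (top-left, top-right, bottom-left, bottom-right) order, deterministically.
    """

    def forward(self, x):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        self._x = x
        out = np.maximum(
            np.maximum(x[:, 0::2, 0::2], x[:, 0::2, 1::2]),
            np.maximum(x[:, 1::2, 0::2], x[:, 1::2, 1::2]),
        )
        self._out = out
        return out

    def backward(self, dy):
        return _pool_backward(self._x, self._out,
                              np.ascontiguousarray(dy, dtype=_F32))


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = _kaiming_uniform(rng, (in_features, out_features), in_features)
        self.b = _kaiming_uniform(rng, (out_features,), in_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for i, layer in enumerate(self.layers):
            out.extend((f"{i}.{n}", v, g) for n, v, g in layer.params())
        return out

    def train(self, mode: bool = True):
        for layer in self.layers:
            layer.train_mode = mode
        return self

    def eval(self):
        return self.train(False)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for i, layer in zip(range(len(self.layers) - 1, -1, -1), reversed(self.layers)):
            if i == 0 and isinstance(layer, Conv2d):
                return layer.backward(dy, need_input_grad=False)
            dy = layer.backward(dy)
        return dy

    def n_parameters(self) -> int:
        return int(sum(v.size for _, v, _ in self.params()))

    def state_dict(self) -> dict:
        state = {n: v.copy() for n, v, _ in self.params()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2d):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for n, v, _ in self.params():
            v[...] = state[n]
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"{i}.running_mean"]
                layer.running_var[...] = state[f"{i}.running_var"]


class Adam:
    """Adam with bias correction (Kingma & Ba defaults unless overridden)."""

    def __init__(self, model: Sequential, lr: float = 1e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = {n: np.zeros_like(v) for n, v, _ in model.params()}
        self.v = {n: np.zeros_like(v) for n, v, _ in model.params()}

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        scale = _F32(self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t))
        for name, value, grad in self.model.params():
            _adam_kernel(value.ravel(), grad.ravel(), self.m[name].ravel(),
                         self.v[name].ravel(), _F32(b1), _F32(b2), scale, _F32(self.eps))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(logits: np.ndarray, y: np.ndarray,
                           class_weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy.

    Loss is the weight-normalized mean ``sum_i w[y_i] * (-log p_i[y_i]) /
    sum_i w[y_i]``, so scaling all class weights by a common factor leaves
    both the loss and its gradient unchanged. Returns (loss, dloss/dlogits).
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    w = np.asarray(class_weights, dtype=np.float64)[y]
    wsum = w.sum()
    loss = float((-w * np.log(np.clip(p[np.arange(n), y], 1e-12, None))).sum() / wsum)
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits.astype(_F32)
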
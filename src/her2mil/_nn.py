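"""Minimal float64 neural-network core: layers, backprop and Adam.

This package trains small networks on CPU, so the layer zoo is deliberately
tiny: 3x3 same-padding convolutions (im2col), 2x2 max pooling, ReLU/Tanh,
global average pooling, dense layers and an identity-skip residual block.
Tensors are NHWC.  Every layer caches what its backward pass needs; the
finite-difference gradient tests in the suite pin the arithmetic down.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: stateless unless it owns parameters."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 init: str = "he"):
        if init == "zero":
            self.w = np.zeros((d_in, d_out))
        else:
            self.w = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        self.b = np.zeros(d_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.dw[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.w.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, g):
        return g * (1.0 - self._y ** 2)


class Conv2d(Layer):
    """3x3 (or kxk) stride-1 same-padding convolution on NHWC tensors."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        fan_in = k * k * c_in
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.w = rng.standard_normal((k * k * c_in, c_out)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def forward(self, x):
        k = self.k
        p = k // 2
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # n,h,w,c,k,k
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, k * k * self.c_in)
        self._cols = cols
        self._in_shape = x.shape
        out = cols @ self.w + self.b
        return out.reshape(n, h, w, self.c_out)

    def backward(self, g):
        n, h, w, _ = self._in_shape
        k, p = self.k, self.k // 2
        gf = g.reshape(n * h * w, self.c_out)
        self.dw[...] = self._cols.T @ gf
        self.db[...] = gf.sum(axis=0)
        dcols = (gf @ self.w.T).reshape(n, h, w, k, k, self.c_in)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.c_in))
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p : p + h, p : p + w, :]


class MaxPool2d(Layer):
    """2x2 stride-2 max pooling; tied maxima share the gradient."""

    def forward(self, x):
        n, h, w, c = x.shape
        assert h % 2 == 0 and w % 2 == 0, "pooling expects even spatial dims"
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        self._mask = mask / np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1)
        self._shape = x.shape
        return out

    def backward(self, g):
        n, h, w, c = self._shape
        gexp = g[:, :, None, :, None, :] * self._mask
        return gexp.reshape(n, h, w, c)


class GlobalAvgPool(Layer):
    """NHWC -> N x C mean over the spatial axes."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g):
        n, h, w, c = self._shape
        return np.broadcast_to(g[:, None, None, :], (n, h, w, c)) / (h * w)


class ResidualBlock(Layer):
    """conv-ReLU-conv with an identity skip, then ReLU (channel-preserving)."""

    def __init__(self, c: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c, c, rng)
        self.conv2 = Conv2d(c, c, rng)
        self.relu1 = ReLU()
        self.relu_out = ReLU()

    def params(self):
        out = {}
        for tag, layer in (("conv1", self.conv1), ("conv2", self.conv2)):
            for k, v in layer.params().items():
                out[f"{tag}.{k}"] = v
        return out

    def grads(self):
        out = {}
        for tag, layer in (("conv1", self.conv1), ("conv2", self.conv2)):
            for k, v in layer.grads().items():
                out[f"{tag}.{k}"] = v
        return out

    def forward(self, x):
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu_out.forward(x + y)

    def backward(self, g):
        g = self.relu_out.backward(g)
        g_branch = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        return g + g_branch


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params().items():
                out[f"{i}.{k}"] = v
        return out

    def grads(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.grads().items():
                out[f"{i}.{k}"] = v
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Max-subtraction stable softmax."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(probs: np.ndarray, y: int) -> float:
    return float(-np.log(max(probs[y], 1e-300)))


class Adam:
    """Adam over a dict of (parameter, gradient) array pairs.

    ``weight_decay`` is classic L2 added to the gradient (the convention the
    reference hyperparameters assume), not decoupled decay.
    """

    def __init__(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
                 lr: float = 1e-4, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-8):
        self.params, self.grad_refs = params, grads
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            g = self.grad_refs[k] + self.weight_decay * p
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
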
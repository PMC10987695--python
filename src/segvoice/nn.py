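"""A small, deterministic feedforward/convolutional network engine.

Implements exactly what the three classifier designs need — dense layers,
3x3 same-padding convolutions, 2x2 max pooling, ReLU, inverted dropout, a
softmax cross-entropy head and Adam — in plain numpy, with full control of
seeding so that (config, data, seed) always reproduces the same weights
and metrics on one machine.  Backpropagation reaches the inputs, which the
interpretation module uses for saliency maps.

Layout conventions: dense inputs are (N, D); image inputs are (N, H, W, C)
channels-last float arrays.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.params = [w.astype(np.float64), np.zeros(n_out)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.params[0].T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout must lie in [0, 1), got {p}")
        self.p, self.rng = p, rng

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Conv2D(Layer):
    """3x3 convolution with stride 1 and same padding, channels-last."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3) -> None:
        super().__init__()
        self.k, self.c_in, self.c_out = k, c_in, c_out
        w = rng.standard_normal((k * k * c_in, c_out)) * np.sqrt(2.0 / (k * k * c_in))
        self.params = [w.astype(np.float64), np.zeros(c_out)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train=False):
        n, h, w, _ = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        cols = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))  # (n,h,w,c,k,k)
        cols = cols.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, -1)
        self._cols, self._in_shape = cols, x.shape
        out = cols @ self.params[0] + self.params[1]
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout):
        n, h, w, _ = self._in_shape
        dflat = dout.reshape(n * h * w, self.c_out)
        self.grads[0][...] = self._cols.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        dcols = (dflat @ self.params[0].T).reshape(n, h, w, self.k, self.k, self.c_in)
        pad = self.k // 2
        dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, self.c_in))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, pad : pad + h, pad : pad + w, :]


class MaxPool2(Layer):
    """2x2 max pooling (even spatial dims required)."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        t = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        t = t.reshape(n, h // 2, w // 2, 4, c)
        self._idx = t.argmax(axis=3)
        self._in_shape = x.shape
        return np.take_along_axis(t, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout):
        n, h, w, c = self._in_shape
        dt = np.zeros((n, h // 2, w // 2, 4, c))
        np.put_along_axis(dt, self._idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dt = dt.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return dt.reshape(n, h, w, c)


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]


class TwoBranch:
    """Two parallel branches whose outputs are concatenated into a head."""

    def __init__(self, branch_a: Sequential, branch_b: Sequential, head: Sequential) -> None:
        self.branch_a, self.branch_b, self.head = branch_a, branch_b, head

    def forward(self, inputs: tuple[np.ndarray, np.ndarray], train=False):
        xa, xb = inputs
        oa = self.branch_a.forward(xa, train=train)
        ob = self.branch_b.forward(xb, train=train)
        self._split = oa.shape[1]
        return self.head.forward(np.concatenate([oa, ob], axis=1), train=train)

    def backward(self, dout):
        dcat = self.head.backward(dout)
        da = self.branch_a.backward(dcat[:, : self._split])
        db = self.branch_b.backward(dcat[:, self._split :])
        return da, db

    @property
    def params(self):
        return self.branch_a.params + self.branch_b.params + self.head.params

    @property
    def grads(self):
        return self.branch_a.grads + self.branch_b.grads + self.head.grads


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-12)))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params, self.lr = params, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def get_weights(net) -> list[np.ndarray]:
    return [p.copy() for p in net.params]


def set_weights(net, weights: list[np.ndarray]) -> None:
    for p, w in zip(net.params, weights):
        p[...] = w
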
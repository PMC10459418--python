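"""Minimal deterministic neural-network engine (numpy).

Implements exactly what the classifier backbones need: 2-D convolution
(im2col), max pooling, dense layers, ReLU, softmax cross-entropy, and
minibatch stochastic gradient descent with momentum.  Everything is seeded
through a single ``numpy.random.Generator``, so identical (data, spec,
config, seed) yields identical parameters and predictions.

Data layout is NCHW float32.
"""

from __future__ import annotations

import numpy as np


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """Unfold k x k patches: (n, c, h, w) -> (n, c*k*k, oh*ow)."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * k * k, oh * ow), oh, ow


def col2im(
    dcols: np.ndarray, shape: tuple[int, int, int, int], k: int, stride: int, pad: int
) -> np.ndarray:
    """Fold patch gradients back onto the (padded) input, summing overlaps."""
    n, c, h, w = shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[
                :, :, i, j
            ]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Layer:
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int, pad: int, rng):
        fan_in = in_ch * k * k
        self.w = (rng.standard_normal((out_ch, fan_in)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.k, self.stride, self.pad = k, stride, pad
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._shape = x.shape
        cols, oh, ow = im2col(x, self.k, self.stride, self.pad)
        self._cols = cols if train else None
        # (oc, f) @ (n, f, p) -> (n, oc, p)
        out = np.matmul(self.w, cols) + self.b[:, None]
        n = x.shape[0]
        return out.reshape(n, -1, oh, ow)

    def backward(self, dout):
        n, oc, oh, ow = dout.shape
        d = dout.reshape(n, oc, oh * ow)
        self.grads[0][...] = np.einsum("nop,nfp->of", d, self._cols)
        self.grads[1][...] = d.sum(axis=(0, 2))
        dcols = np.matmul(self.w.T, d)
        return col2im(dcols, self._shape, self.k, self.stride, self.pad)


class MaxPool2D(Layer):
    def __init__(self, k: int, stride: int):
        self.k, self.stride = k, stride
        self.params, self.grads = [], []

    def forward(self, x, train):
        self._shape = x.shape
        n, c, h, w = x.shape
        cols, oh, ow = im2col(x, self.k, self.stride, 0)
        cols = cols.reshape(n, c, self.k * self.k, oh * ow)
        self._argmax = cols.argmax(axis=2)
        self._ohow = (oh, ow)
        return cols.max(axis=2).reshape(n, c, oh, ow)

    def backward(self, dout):
        n, c, oh, ow = dout.shape
        d = dout.reshape(n, c, oh * ow)
        dcols = np.zeros((n, c, self.k * self.k, oh * ow), dtype=dout.dtype)
        np.put_along_axis(dcols, self._argmax[:, :, None, :], d[:, :, None, :], axis=2)
        return col2im(
            dcols.reshape(n, c * self.k * self.k, oh * ow),
            self._shape,
            self.k,
            self.stride,
            0,
        )


class ReLU(Layer):
    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng):
        self.w = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(
            np.float32
        )
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


class Network:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p[...] = s


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.log(probs[np.arange(len(y)), y] + eps).mean())


class MomentumSGD:
    """Classical momentum: v <- mu*v - lr*g; p <- p + v."""

    def __init__(self, params: list[np.ndarray], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, v in zip(self.params, grads, self.velocity, strict=True):
            v *= self.momentum
            v -= self.lr * g
            p += v
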
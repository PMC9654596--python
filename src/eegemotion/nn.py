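"""Minimal trainable neural-network engine for 1-D convolutional models.

Implements exactly the layer vocabulary the classifiers need — Conv1D
(same padding, stride 1), Dense, ReLU, MaxPool1D, Dropout, Flatten, a
residual block with an optional 1x1 projection on the skip path, and a
softmax + categorical cross-entropy head — together with the Adam
optimizer.  Tensors are channels-last: (batch, length, channels).

Gradients are computed layer-by-layer with hand-derived backward passes;
correctness is pinned by finite-difference tests.  The engine is
deliberately small rather than general: stride-1 same-padded convolutions
and non-overlapping pooling are all the model family uses.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv1D", "Dense", "ReLU", "MaxPool1D", "Dropout", "Flatten",
    "Residual", "Softmax", "Network", "Adam", "softmax_cross_entropy",
]


class Layer:
    """Forward/backward node.  Subclasses with weights expose params()/grads()."""

    trainable: bool = False

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list:
        return []

    def grads(self) -> list:
        return []

    def n_params(self) -> int:
        return sum(p.size for p in self.params())


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv1D(Layer):
    """Stride-1 convolution with odd kernel and same padding.

    Weight shape (kernel, in_channels, filters); bias (filters,).
    """

    trainable = True

    def __init__(self, filters: int, kernel_size: int, in_channels: int,
                 rng: np.random.Generator):
        if kernel_size % 2 == 0:
            raise ValueError("same padding requires an odd kernel size")
        self.filters = filters
        self.kernel_size = kernel_size
        self.in_channels = in_channels
        self.w = _he_init(rng, (kernel_size, in_channels, filters),
                          kernel_size * in_channels)
        self.b = np.zeros(filters)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        pad = self.kernel_size // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        # (batch, length, kernel, channels)
        return sliding_window_view(xp, self.kernel_size, axis=1).transpose(0, 1, 3, 2)

    def forward(self, x, training=False):
        self._x = x
        cols = self._im2col(x)                       # (N, L, K, C)
        n, length = cols.shape[:2]
        self._cols = cols.reshape(n, length, -1)     # (N, L, K*C)
        wmat = self.w.reshape(-1, self.filters)      # (K*C, F)
        return self._cols @ wmat + self.b

    def backward(self, grad):
        n, length, _ = grad.shape
        wmat = self.w.reshape(-1, self.filters)
        self.dw = (
            self._cols.reshape(-1, wmat.shape[0]).T @ grad.reshape(-1, self.filters)
        ).reshape(self.w.shape)
        self.db = grad.sum(axis=(0, 1))
        dcols = grad @ wmat.T                        # (N, L, K*C)
        dcols = dcols.reshape(n, length, self.kernel_size, self.in_channels)
        pad = self.kernel_size // 2
        dx = np.zeros((n, length + 2 * pad, self.in_channels))
        for k in range(self.kernel_size):            # scatter-add, kernel is small
            dx[:, k:k + length] += dcols[:, :, k]
        return dx[:, pad:pad + length]

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Dense(Layer):
    trainable = True

    def __init__(self, units: int, in_features: int, rng: np.random.Generator):
        self.w = _he_init(rng, (in_features, units), in_features)
        self.b = np.zeros(units)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; trailing remainder samples are dropped."""

    def __init__(self, pool_size: int):
        self.pool_size = pool_size

    def forward(self, x, training=False):
        n, length, c = x.shape
        p = self.pool_size
        out_len = length // p
        self._in_shape = x.shape
        xt = x[:, :out_len * p].reshape(n, out_len, p, c)
        self._argmax = xt.argmax(axis=2)             # (N, out, C)
        return xt.max(axis=2)

    def backward(self, grad):
        n, out_len, c = grad.shape
        p = self.pool_size
        dxt = np.zeros((n, out_len, p, c))
        ni, oi, ci = np.ogrid[:n, :out_len, :c]
        dxt[ni, oi, self._argmax, ci] = grad
        dx = np.zeros(self._in_shape)
        dx[:, :out_len * p] = dxt.reshape(n, out_len * p, c)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Residual(Layer):
    """y = main(x) + skip(x); skip is identity or a 1x1 projection conv.

    The additional path gives gradients a shortcut around the main
    convolution, the standard remedy for vanishing signal in deeper
    stacks.
    """

    def __init__(self, main: list, skip: list | None = None):
        self.main = main
        self.skip = skip or []

    def forward(self, x, training=False):
        h = x
        for layer in self.main:
            h = layer.forward(h, training)
        s = x
        for layer in self.skip:
            s = layer.forward(s, training)
        return h + s

    def backward(self, grad):
        gh = grad
        for layer in reversed(self.main):
            gh = layer.backward(gh)
        gs = grad
        for layer in reversed(self.skip):
            gs = layer.backward(gs)
        return gh + gs

    def params(self):
        return [p for l in self.main + self.skip for p in l.params()]

    def grads(self):
        return [g for l in self.main + self.skip for g in l.grads()]


class Softmax(Layer):
    """Row-wise softmax.  Backward assumes the combined CE gradient is
    injected upstream (see ``softmax_cross_entropy``), so it is identity."""

    def forward(self, x, training=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self.probs = e / e.sum(axis=-1, keepdims=True)
        return self.probs

    def backward(self, grad):
        return grad


def softmax_cross_entropy(probs: np.ndarray, onehot: np.ndarray):
    """Mean categorical cross-entropy and the gradient w.r.t. logits.

    ``probs`` must come from the network's Softmax layer; the returned
    gradient (probs - y)/n is with respect to the pre-softmax logits and
    must be fed through the Softmax's identity backward.
    """
    n = probs.shape[0]
    eps = 1e-12
    loss = -np.sum(onehot * np.log(probs + eps)) / n
    return loss, (probs - onehot) / n


class Network:
    """A sequential stack of layers (residual blocks are single layers)."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, x, batch_size: int = 1024) -> np.ndarray:
        out = [self.forward(x[i:i + batch_size], training=False)
               for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(out) if out else np.empty((0, 2))

    def predict(self, x, batch_size: int = 1024) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def get_weights(self) -> list:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            p[...] = w

    def save_weights(self, path) -> None:
        """Checkpoint all parameter arrays to an .npz file."""
        np.savez(path, *self.params())

    def load_weights(self, path) -> None:
        with np.load(path) as archive:
            self.set_weights([archive[k] for k in archive.files])


class Adam:
    """Adaptive-moment estimation with the standard bias correction."""

    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
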
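"""Minimal NumPy neural-network engine used by the peak classifier.

Implements exactly the layer vocabulary the model needs — 1-D valid
convolution (im2col + BLAS matmul), leaky ReLU, batch normalization,
dropout, dense layers — plus the Adam optimizer and binary cross-entropy
with logits. All randomness (initialization, shuffling, dropout masks)
flows through a single numpy Generator so training is reproducible from a
seed. Arrays are float32 throughout.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

DTYPE = np.float32


class Layer:
    """Base layer: forward/backward plus parameter access."""

    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []

    def state(self) -> List[np.ndarray]:
        """Non-trainable buffers (e.g. batch-norm running stats)."""
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid (unpadded) 1-D convolution, stride 1.

    Input (N, L, C_in) -> output (N, L - K + 1, C_out).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        self.kernel = kernel
        scale = np.sqrt(2.0 / (kernel * in_ch))  # He initialization
        self.W = (rng.standard_normal((kernel * in_ch, out_ch)) * scale).astype(DTYPE)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: Optional[np.ndarray] = None
        self._in_shape: Optional[Tuple[int, ...]] = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training):
        n, length, cin = x.shape
        k = self.kernel
        lout = length - k + 1
        # (N, Lout, K, Cin) view, then fold K*Cin for one big matmul
        cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(n, lout, k * cin)
        self._cols = cols
        self._in_shape = x.shape
        return cols @ self.W + self.b

    def backward(self, dy):
        n, lout, cout = dy.shape
        k = self.kernel
        _, length, cin = self._in_shape
        cols2 = self._cols.reshape(-1, k * cin)
        dy2 = dy.reshape(-1, cout)
        self.dW[...] = cols2.T @ dy2
        self.db[...] = dy2.sum(axis=0)
        dcols = (dy2 @ self.W.T).reshape(n, lout, k, cin)
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        for i in range(k):
            dx[:, i:i + lout, :] += dcols[:, :, i, :]
        return dx


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha
        self._mask: Optional[np.ndarray] = None

    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x).astype(DTYPE)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy).astype(DTYPE)


class BatchNorm(Layer):
    """Per-channel batch normalization over all leading axes.

    For (N, L, C) inputs statistics pool over N and L; for (N, C) over N.
    Inference uses running statistics so scoring is deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def state(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = (self.momentum * self.running_mean
                                      + (1 - self.momentum) * mean)
            self.running_var[...] = (self.momentum * self.running_var
                                     + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._xhat, self._inv, self._axes = xhat, inv, axes
            self._m = np.prod([x.shape[a] for a in axes])
        return (self.gamma * xhat + self.beta).astype(DTYPE)

    def backward(self, dy):
        xhat, inv, axes, m = self._xhat, self._inv, self._axes, self._m
        self.dgamma[...] = (dy * xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        dx = (inv / m) * (m * dxhat
                          - dxhat.sum(axis=axes)
                          - xhat * (dxhat * xhat).sum(axis=axes))
        return dx.astype(DTYPE)


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask: Optional[np.ndarray] = None

    def forward(self, x, training):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return (x * self._mask).astype(DTYPE)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(DTYPE)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def state(self):
        return [s for l in self.layers for s in l.state()]

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class MultiBranchNet:
    """Parallel branches whose flattened outputs concatenate into one head."""

    def __init__(self, branches: Dict[str, Sequential], head: Sequential):
        self.branches = dict(branches)
        self.head = head
        self._widths: Optional[Dict[str, int]] = None

    @property
    def branch_names(self) -> List[str]:
        return sorted(self.branches)

    def params(self):
        out = []
        for name in self.branch_names:
            out.extend(self.branches[name].params())
        out.extend(self.head.params())
        return out

    def grads(self):
        out = []
        for name in self.branch_names:
            out.extend(self.branches[name].grads())
        out.extend(self.head.grads())
        return out

    def state(self):
        out = []
        for name in self.branch_names:
            out.extend(self.branches[name].state())
        out.extend(self.head.state())
        return out

    def forward(self, inputs: Dict[str, np.ndarray], training: bool) -> np.ndarray:
        outs = []
        widths = {}
        for name in self.branch_names:
            y = self.branches[name].forward(inputs[name].astype(DTYPE), training)
            widths[name] = y.shape[1]
            outs.append(y)
        self._widths = widths
        z = np.concatenate(outs, axis=1)
        return self.head.forward(z, training)[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        dz = self.head.backward(dlogit[:, None])
        start = 0
        for name in self.branch_names:
            w = self._widths[name]
            self.branches[name].backward(dz[:, start:start + w])
            start += w


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> float:
    """Numerically stable mean binary cross-entropy."""
    z = logits.astype(np.float64)
    return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))


class Adam:
    def __init__(self, params: List[np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def snapshot(arrays: List[np.ndarray]) -> List[np.ndarray]:
    return [a.copy() for a in arrays]


def restore(arrays: List[np.ndarray], saved: List[np.ndarray]) -> None:
    for a, s in zip(arrays, saved):
        a[...] = s
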
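"""NumPy kernels for 3D valid convolutions with explicit backprop.

Tensors are channels-last: ``(batch, d, h, w, channels)``.  Convolutions are
unpadded ("valid"), im2col + BLAS matmul.  Only what the segmentation
network needs is implemented: 3x3x3 conv, pointwise (1x1x1) conv, leaky
ReLU, nearest-neighbour gather-upsampling, softmax cross-entropy, Adam.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv3D",
    "Pointwise",
    "LeakyReLU",
    "GatherUpsample",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


class Layer:
    def params(self):
        return []

    def forward(self, x, keep=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


def _shift_conv(x, w, bias=None):
    """Valid convolution as k^3 accumulated shifted matmuls.

    ``x``: (B, D, H, W, C_in); ``w``: (C_in, k, k, k, C_out).  Avoids the
    im2col blow-up (k^3 duplication of the input), which dominates run
    time for whole-volume inference.
    """
    k = w.shape[1]
    do, ho, wo = (s - k + 1 for s in x.shape[1:4])
    y = np.zeros((x.shape[0], do, ho, wo, w.shape[-1]), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                y += x[:, i : i + do, j : j + ho, l : l + wo, :] @ w[:, i, j, l, :]
    if bias is not None:
        y += bias
    return y


class Conv3D(Layer):
    """Valid 3D convolution; weight layout (C_in, k, k, k, C_out)."""

    def __init__(self, c_in, c_out, k=3, rng=None):
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        rng = rng or np.random.default_rng()
        fan_in = c_in * k**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in, k, k, k, c_out))
        self.W = Param(w)
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, keep=False):
        x = np.asarray(x, dtype=np.float32)
        y = _shift_conv(x, self.W.value, self.b.value)
        if keep:
            self._cache = x
        return y

    def backward(self, g):
        x = self._cache
        k = self.k
        do, ho, wo = g.shape[1:4]
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = x[:, i : i + do, j : j + ho, l : l + wo, :]
                    self.W.grad[:, i, j, l, :] += np.tensordot(
                        xs, g, axes=([0, 1, 2, 3], [0, 1, 2, 3])
                    )
        self.b.grad += g.sum(axis=(0, 1, 2, 3))
        # grad w.r.t. input: full correlation = valid conv of the padded
        # grad with the spatially flipped, channel-transposed kernel
        p = k - 1
        gp = np.pad(g, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        w_rot = np.ascontiguousarray(
            self.W.value[:, ::-1, ::-1, ::-1, :].transpose(4, 1, 2, 3, 0)
        )
        self._cache = None
        return _shift_conv(gp, w_rot)


class Pointwise(Layer):
    """1x1x1 convolution: a per-voxel linear map over channels."""

    def __init__(self, c_in, c_out, rng=None):
        rng = rng or np.random.default_rng()
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, keep=False):
        if keep:
            self._cache = x
        return x @ self.W.value + self.b.value

    def backward(self, g):
        x = self._cache
        c_in = x.shape[-1]
        c_out = g.shape[-1]
        self.W.grad += x.reshape(-1, c_in).T @ g.reshape(-1, c_out)
        self.b.grad += g.reshape(-1, c_out).sum(axis=0)
        self._cache = None
        return g @ self.W.value.T


class LeakyReLU(Layer):
    def __init__(self, slope=0.1):
        self.slope = slope
        self._mask = None

    def forward(self, x, keep=False):
        mask = x > 0
        if keep:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, g):
        out = np.where(self._mask, g, self.slope * g)
        self._mask = None
        return out


class GatherUpsample(Layer):
    """Nearest-neighbour upsampling by per-sample index lookup.

    ``idx`` is an int array (B, 3, T): for sample b, output voxel
    (i, j, l) reads feature cell (idx[b,0,i], idx[b,1,j], idx[b,2,l]).
    """

    def __init__(self):
        self._cache = None

    def forward(self, x, idx, keep=False):
        b = x.shape[0]
        out = np.empty(
            (b, idx.shape[2], idx.shape[2], idx.shape[2], x.shape[-1]), dtype=x.dtype
        )
        for i in range(b):
            sel = np.ix_(idx[i, 0], idx[i, 1], idx[i, 2])
            out[i] = x[i][sel]
        if keep:
            self._cache = (x.shape, idx)
        return out

    def backward(self, g):
        x_shape, idx = self._cache
        dx = np.zeros(x_shape, dtype=g.dtype)
        for i in range(g.shape[0]):
            sel = np.ix_(idx[i, 0], idx[i, 1], idx[i, 2])
            np.add.at(dx[i], sel, g[i])
        self._cache = None
        return dx


def softmax(logits):
    """Softmax over the trailing class axis (float64 internally)."""
    z = logits.astype(np.float64)
    z -= z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy over all voxels; returns (loss, dlogits, probs).

    ``logits``: (..., n_classes); ``labels``: int array of matching
    leading shape.
    """
    flat = logits.reshape(-1, logits.shape[-1]).astype(np.float64)
    lab = np.asarray(labels).reshape(-1)
    z = flat - flat.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = lab.shape[0]
    loss = float(-np.log(np.maximum(p[np.arange(n), lab], 1e-300)).mean())
    grad = p.copy()
    grad[np.arange(n), lab] -= 1.0
    grad /= n
    return loss, grad.reshape(logits.shape).astype(np.float32), p.reshape(logits.shape)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
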
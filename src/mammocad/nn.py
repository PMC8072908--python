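"""Minimal NumPy neural-network layers used by the patch classifier.

Implements exactly what the mass/background classifier needs — stride-1
"same" convolution (im2col + GEMM), batch normalization, ReLU, 2x2 max
pooling, dense layers, and softmax cross-entropy with plain SGD — in
float32 on CPU.

Layout is NHWC and every layer keeps persistent scratch buffers that are
reused across minibatches: on a single-core machine the dominant cost of a
naive implementation is allocating and first-touching hundreds of MB of
fresh temporaries per batch, not the GEMMs themselves.  All randomness goes
through a caller-supplied numpy Generator so training is reproducible from
a seed.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import blas as _blas


def _gemm_acc(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> None:
    """c += a @ b without temporaries (C-contiguous operands).

    Uses the identity (a@b)^T = b^T @ a^T so that BLAS sees
    Fortran-contiguous arrays and accumulates in place with beta = 1.
    """
    _blas.sgemm(1.0, b.T, a.T, beta=1.0, c=c.T, overwrite_c=1)

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Flatten",
    "Dense",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
]


class _Scratch:
    """Named persistent float32 work buffers, sliced to the current batch."""

    def __init__(self):
        self._store: dict[str, np.ndarray] = {}

    def get(self, name: str, shape: tuple[int, ...], dtype=np.float32) -> np.ndarray:
        buf = self._store.get(name)
        if buf is None or buf.dtype != np.dtype(dtype) or buf.shape[1:] != shape[1:] \
                or buf.shape[0] < shape[0]:
            buf = np.empty(shape, dtype=dtype)
            self._store[name] = buf
        return buf[: shape[0]]


class Layer:
    trainable: tuple[str, ...] = ()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params_and_grads(self):
        for name in self.trainable:
            yield getattr(self, name), getattr(self, "d_" + name)


class Conv2d(Layer):
    """Stride-1 'same' convolution (odd kernel), NHWC.

    Single-channel input uses classic im2col + one GEMM.  Multi-channel
    input instead accumulates one GEMM per kernel offset over a contiguous
    shifted copy of the padded input — this avoids materializing the
    k²-times-larger patch matrix, whose assembly and footprint dominate on
    a single core.  The weight matrix is stored (k·k·C_in, C_out) with
    offset-major rows, so both paths share one parameterization.
    """

    trainable = ("weight", "bias")

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, compute_dx: bool = True):
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        k = kernel_size
        fan_in = in_channels * k * k
        scale = np.sqrt(2.0 / fan_in)  # He initialization (ReLU follows)
        self.weight = (rng.standard_normal((fan_in, out_channels)) * scale).astype(np.float32)
        self.bias = np.zeros(out_channels, dtype=np.float32)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = k
        self.pad = k // 2
        self.compute_dx = compute_dx
        self._s = _Scratch()

    def _offsets(self):
        return [(ki, kj) for ki in range(self.k) for kj in range(self.k)]

    def _pad_input(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.pad
        xp = self._s.get("xp", (n, h + 2 * p, w + 2 * p, c))
        xp[:, :p].fill(0.0)
        xp[:, -p:].fill(0.0)
        xp[:, :, :p].fill(0.0)
        xp[:, :, -p:].fill(0.0)
        np.copyto(xp[:, p:p + h, p:p + w, :], x)
        return xp

    def _build_cols(self, xp: np.ndarray, n: int, h: int, w: int) -> np.ndarray:
        c = self.in_channels
        cols = self._s.get("cols", (n, h, w, self.k * self.k * c))
        for idx, (ki, kj) in enumerate(self._offsets()):
            np.copyto(cols[..., idx * c:(idx + 1) * c],
                      xp[:, ki:ki + h, kj:kj + w, :])
        return cols

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        xp = self._pad_input(x)
        y = self._s.get("y", (n, h, w, self.out_channels))
        y2d = y.reshape(n * h * w, self.out_channels)
        if c == 1:
            cols = self._build_cols(xp, n, h, w)
            np.matmul(cols.reshape(n * h * w, -1), self.weight, out=y2d)
        else:
            wk = self.weight.reshape(self.k * self.k, c, self.out_channels)
            slc = self._s.get("slc", (n, h, w, c))
            for idx, (ki, kj) in enumerate(self._offsets()):
                np.copyto(slc, xp[:, ki:ki + h, kj:kj + w, :])
                s2d = slc.reshape(n * h * w, c)
                if idx == 0:
                    np.matmul(s2d, wk[idx], out=y2d)
                else:
                    _gemm_acc(s2d, np.ascontiguousarray(wk[idx]), y2d)
        y += self.bias
        if train:
            self._xp = xp
            self._shape = (n, h, w)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w = self._shape
        c = self.in_channels
        xp = self._xp
        dym = dy.reshape(n * h * w, self.out_channels)
        self.d_bias = dym.sum(axis=0)
        p = self.pad
        if c == 1:
            # cols were clobbered by nothing, but rebuild for safety
            cols = self._build_cols(xp, n, h, w)
            self.d_weight = cols.reshape(n * h * w, -1).T @ dym
            if not self.compute_dx:
                return None
            dcols = cols
            np.matmul(dym, self.weight.T, out=dcols.reshape(n * h * w, -1))
            dxp = self._s.get("dxp", (n, h + 2 * p, w + 2 * p, c))
            dxp.fill(0.0)
            for idx, (ki, kj) in enumerate(self._offsets()):
                dxp[:, ki:ki + h, kj:kj + w, :] += dcols[..., idx * c:(idx + 1) * c]
            return dxp[:, p:p + h, p:p + w, :]
        wk = self.weight.reshape(self.k * self.k, c, self.out_channels)
        self.d_weight = self._s.get("dw", self.weight.shape)
        dwk = self.d_weight.reshape(self.k * self.k, c, self.out_channels)
        slc = self._s.get("slc", (n, h, w, c))
        if self.compute_dx:
            dxp = self._s.get("dxp", (n, h + 2 * p, w + 2 * p, c))
            dxp.fill(0.0)
            tmp = self._s.get("dtmp", (n, h, w, c))
            t2d = tmp.reshape(n * h * w, c)
        for idx, (ki, kj) in enumerate(self._offsets()):
            np.copyto(slc, xp[:, ki:ki + h, kj:kj + w, :])
            np.matmul(slc.reshape(n * h * w, c).T, dym, out=dwk[idx])
            if self.compute_dx:
                np.matmul(dym, wk[idx].T, out=t2d)
                dxp[:, ki:ki + h, kj:kj + w, :] += tmp
        if not self.compute_dx:
            return None
        return dxp[:, p:p + h, p:p + w, :]


class BatchNorm2d(Layer):
    trainable = ("gamma", "beta")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._s = _Scratch()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        m = x.shape[0] * x.shape[1] * x.shape[2]
        if train:
            mean = x.mean(axis=(0, 1, 2))
            sq = np.einsum("nhwc,nhwc->c", x, x, optimize=True) / m
            var = np.maximum(sq - mean * mean, 0.0)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        scale = (self.gamma * inv_std).astype(np.float32)
        shift = (self.beta - mean * scale).astype(np.float32)
        y = self._s.get("y", x.shape)
        np.multiply(x, scale, out=y)
        y += shift
        if train:
            self._x = x
            self._mean = mean.astype(np.float32)
            self._inv_std = inv_std.astype(np.float32)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, mean, inv_std = self._x, self._mean, self._inv_std
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        xhat = self._s.get("xhat", x.shape)
        np.subtract(x, mean, out=xhat)
        xhat *= inv_std
        self.d_gamma = np.einsum("nhwc,nhwc->c", dy, xhat, optimize=True)
        self.d_beta = dy.sum(axis=(0, 1, 2))
        # reuse xhat as the output buffer
        dx = xhat
        dx *= (self.d_gamma / m).astype(np.float32)
        dx += (self.d_beta / m).astype(np.float32)
        np.subtract(dy, dx, out=dx)
        dx *= (self.gamma * inv_std).astype(np.float32)
        self._x = None
        return dx


class ReLU(Layer):
    """In-place rectification (the input buffer is overwritten)."""

    def __init__(self):
        self._s = _Scratch()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        np.maximum(x, 0.0, out=x)
        if train:
            mask = self._s.get("mask", x.shape, dtype=bool)
            np.greater(x, 0.0, out=mask)
            self._mask = mask
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy *= self._mask
        return dy


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2, NHWC; odd trailing rows/cols are dropped.

    Backward routes gradients by value equality; in the measure-zero event
    of an exact tie within a window both cells receive the gradient.
    """

    def __init__(self):
        self._s = _Scratch()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        v = x[:, : h2 * 2, : w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        m1 = self._s.get("m1", (n, h2, w2, 2, c))
        np.max(v, axis=2, out=m1)
        y = self._s.get("y", (n, h2, w2, c))
        np.max(m1, axis=3, out=y)
        if train:
            self._x = x
            self._m1 = m1
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, m1, y = self._x, self._m1, self._y
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        # stage 2: route dy to the winning row-max of the two candidates
        d1 = self._s.get("d1", (n, h2, w2, 2, c))
        eq1 = self._s.get("eq1", (n, h2, w2, 2, c), dtype=bool)
        np.equal(m1, y[:, :, :, None, :], out=eq1)
        np.multiply(eq1, dy[:, :, :, None, :], out=d1)
        # stage 1: route within each 2-row pair
        dx = self._s.get("dx", (n, h, w, c))
        dx.fill(0.0)
        v = x[:, : h2 * 2, : w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        dv = dx[:, : h2 * 2, : w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        eq0 = self._s.get("eq0", (n, h2, 2, w2, 2, c), dtype=bool)
        np.equal(v, m1[:, :, None, :, :, :], out=eq0)
        np.multiply(eq0, d1[:, :, None, :, :, :], out=dv)
        self._x = None
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    trainable = ("weight", "bias")

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)
        self.weight = (rng.standard_normal((in_features, out_features)) * scale).astype(np.float32)
        self.bias = np.zeros(out_features, dtype=np.float32)
        self._s = _Scratch()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x.copy()
        return x @ self.weight + self.bias

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.d_weight = self._s.get("dw", self.weight.shape)
        np.matmul(self._x.T, dy, out=self.d_weight)
        self.d_bias = dy.sum(axis=0)
        dx = dy @ self.weight.T
        self._x = None
        return dx


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
            if dy is None:
                break

    def sgd_step(self, lr: float) -> None:
        for layer in self.layers:
            for param, grad in layer.params_and_grads():
                grad = np.asarray(grad, dtype=param.dtype)
                grad *= lr  # grads are not reused after the step
                param -= grad

    def n_parameters(self) -> int:
        return sum(getattr(layer, name).size
                   for layer in self.layers for name in layer.trainable)

    def release_buffers(self) -> None:
        """Drop scratch/activation buffers (frees most of training's RSS)."""
        for layer in self.layers:
            s = getattr(layer, "_s", None)
            if s is not None:
                s._store.clear()
            for name in ("_x", "_xp", "_m1", "_y", "_mask"):
                if hasattr(layer, name):
                    setattr(layer, name, None)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    grad = probs.astype(np.float32)
    grad[np.arange(n), labels] -= 1.0
    grad /= n
    return float(loss), grad
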
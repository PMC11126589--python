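"""Minimal 1-D convolutional network framework on numpy.

Implements exactly the pieces the signal classifiers need — 1-D
convolution (strided, dilated, causal), ReLU, max-pooling, batch norm,
dropout, global average pooling, a linear head, basic residual blocks,
dilated causal residual blocks, binary cross-entropy on logits, and Adam —
with explicit forward/backward passes. Convolutions are lowered to BLAS
matrix products via im2col, which is what makes CPU training of the
full-size classifiers practical.

Tensors are ``float32`` with layout ``(batch, channels, length)``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)


class Layer:
    """Base layer: forward caches what backward needs."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trained state that must survive save/load (e.g. BN stats)."""
        return []


class Conv1d(Layer):
    """1-D convolution. ``padding`` is 'valid', 'same' (stride-1 only) or
    'causal' (left padding of dilation*(k-1), preserving length)."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 dilation: int = 1, padding: str = "valid",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k
        w = rng.standard_normal((c_out, c_in, k)) * np.sqrt(2.0 / fan_in)
        self.w = Param(w)
        self.b = Param(np.zeros(c_out))
        self.k, self.stride, self.dilation, self.padding = k, stride, dilation, padding
        self.c_in, self.c_out = c_in, c_out

    def _pads(self) -> tuple[int, int]:
        span = self.dilation * (self.k - 1)
        if self.padding == "valid":
            return 0, 0
        if self.padding == "same":
            return span // 2, span - span // 2
        if self.padding == "causal":
            return span, 0
        raise ValueError(f"unknown padding {self.padding!r}")

    def out_length(self, L: int) -> int:
        pl, pr = self._pads()
        return (L + pl + pr - self.dilation * (self.k - 1) - 1) // self.stride + 1

    def forward(self, x, training=False):
        N, C, L = x.shape
        pl, pr = self._pads()
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else x
        Lo = self.out_length(L)
        if Lo < 1:
            raise ValueError(f"input length {L} too short for kernel {self.k}")
        # im2col: gather (N, C, k, Lo) with one contiguous-stride copy per
        # kernel tap, then contract (c, k) in a batched GEMM over N
        cols = np.empty((N, C, self.k, Lo), dtype=DTYPE)
        for i in range(self.k):
            start = i * self.dilation
            cols[:, :, i, :] = xp[:, :, start:start + self.stride * Lo:self.stride]
        cols3 = cols.reshape(N, C * self.k, Lo)
        w2 = self.w.data.reshape(self.c_out, C * self.k)
        # short feature maps with many channels: merge the batch into one
        # GEMM so the (large) weight matrix is read once, not once per item
        merge = N * Lo <= 8192
        if merge:
            cols_flat = np.ascontiguousarray(cols3.transpose(1, 0, 2)) \
                .reshape(C * self.k, N * Lo)
            y = (w2 @ cols_flat).reshape(self.c_out, N, Lo).transpose(1, 0, 2) \
                + self.b.data[None, :, None]
            self._cache = (cols3, cols_flat, x.shape, Lo)
        else:
            y = np.matmul(w2, cols3) + self.b.data[None, :, None]
            self._cache = (cols3, None, x.shape, Lo)
        return np.ascontiguousarray(y)

    def backward(self, dy):
        cols3, cols_flat, x_shape, Lo = self._cache
        N, C, L = x_shape
        w2 = self.w.data.reshape(self.c_out, C * self.k)
        if cols_flat is not None:
            dy_flat = np.ascontiguousarray(dy.transpose(1, 0, 2)) \
                .reshape(self.c_out, N * Lo)
            self.w.grad += (dy_flat @ cols_flat.T).reshape(self.w.data.shape)
            self.b.grad += dy_flat.sum(axis=1)
            dcols = (w2.T @ dy_flat).reshape(C * self.k, N, Lo) \
                .transpose(1, 0, 2).reshape(N, C, self.k, Lo)
        else:
            self.w.grad += np.tensordot(dy, cols3, axes=([0, 2], [0, 2])) \
                .reshape(self.w.data.shape)
            self.b.grad += dy.sum(axis=(0, 2))
            dcols = np.matmul(w2.T, dy).reshape(N, C, self.k, Lo)
        pl, pr = self._pads()
        dxp = np.zeros((N, C, L + pl + pr), dtype=DTYPE)
        for i in range(self.k):
            start = i * self.dilation
            dxp[:, :, start:start + self.stride * Lo:self.stride] += dcols[:, :, i, :]
        return dxp[:, :, pl:L + pl] if (pl or pr) else dxp

    def params(self):
        return [self.w, self.b]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """Max pooling with kernel 2, stride 2 (a trailing odd sample is
    dropped, so the output length is floor(L/2))."""

    def forward(self, x, training=False):
        N, C, L = x.shape
        Lo = L // 2
        if Lo < 1:
            raise ValueError(f"input length {L} too short to pool")
        a = x[:, :, 0:2 * Lo:2]
        b = x[:, :, 1:2 * Lo:2]
        self._left = a >= b  # ties break to the earlier sample
        self._in_len = L
        return np.where(self._left, a, b)

    def backward(self, dy):
        N, C, Lo = dy.shape
        dx = np.zeros((N, C, self._in_len), dtype=DTYPE)
        dx[:, :, 0:2 * Lo:2] = np.where(self._left, dy, 0)
        dx[:, :, 1:2 * Lo:2] = np.where(self._left, 0, dy)
        return dx


class BatchNorm1d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, training, x.shape)
        return self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]

    def backward(self, dy):
        xhat, inv, training, shape = self._cache
        N, C, L = shape
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma.data[None, :, None]
        if not training:
            return dxhat * inv[None, :, None]
        m = N * L
        term = (dxhat - dxhat.mean(axis=(0, 2), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True) / m)
        return term * inv[None, :, None]

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p, self.rng = p, rng

    def forward(self, x, training=False):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(DTYPE)

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class GlobalAvgPool(Layer):
    """Channel-wise mean over time; what makes the heads length-agnostic."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=2)

    def backward(self, dy):
        N, C, L = self._shape
        return np.broadcast_to(dy[:, :, None] / L, self._shape).astype(DTYPE)


class LastTimestep(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return np.ascontiguousarray(x[:, :, -1])

    def backward(self, dy):
        dx = np.zeros(self._shape, dtype=DTYPE)
        dx[:, :, -1] = dy
        return dx


class Linear(Layer):
    """Fully-connected layer. ``scale=0`` zero-initializes the weights,
    the right choice for a classification head (the initial probability is
    then exactly 0.5 regardless of feature magnitude)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 scale: float | None = None):
        rng = rng or np.random.default_rng(0)
        if scale is None:
            scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.standard_normal((n_out, n_in)) * scale)
        self.b = Param(np.zeros(n_out))

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.data.T + self.b.data

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.data

    def params(self):
        return [self.w, self.b]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def buffers(self):
        return [b for layer in self.layers for b in layer.buffers()]


class _ResidualBase(Layer):
    """Shared add-and-rectify plumbing for residual blocks."""

    main: Sequential
    shortcut: Sequential | None

    def forward(self, x, training=False):
        y = self.main.forward(x, training=training)
        s = x if self.shortcut is None else self.shortcut.forward(x, training=training)
        out = y + s
        self._mask = out > 0
        return out * self._mask

    def backward(self, dy):
        dy = dy * self._mask
        dx = self.main.backward(dy)
        dx = dx + (dy if self.shortcut is None else self.shortcut.backward(dy))
        return dx

    def params(self):
        p = self.main.params()
        if self.shortcut is not None:
            p += self.shortcut.params()
        return p

    def buffers(self):
        b = self.main.buffers()
        if self.shortcut is not None:
            b += self.shortcut.buffers()
        return b


class BasicResidualBlock(_ResidualBase):
    """conv-BN-ReLU-conv-BN with identity (or 1x1-conv) shortcut."""

    def __init__(self, c_in: int, c_out: int, k: int = 3,
                 rng: np.random.Generator | None = None):
        self.main = Sequential(
            Conv1d(c_in, c_out, k, padding="same", rng=rng),
            BatchNorm1d(c_out),
            ReLU(),
            Conv1d(c_out, c_out, k, padding="same", rng=rng),
            BatchNorm1d(c_out),
        )
        self.shortcut = None if c_in == c_out else Sequential(
            Conv1d(c_in, c_out, 1, rng=rng), BatchNorm1d(c_out))


class TCNBlock(_ResidualBase):
    """Two dilated causal convolutions with dropout and a residual skip."""

    def __init__(self, c_in: int, c_out: int, k: int, dilation: int,
                 dropout: float, rng: np.random.Generator):
        self.dilation = dilation
        self.kernel = k
        self.main = Sequential(
            Conv1d(c_in, c_out, k, dilation=dilation, padding="causal", rng=rng),
            ReLU(),
            Dropout(dropout, rng),
            Conv1d(c_out, c_out, k, dilation=dilation, padding="causal", rng=rng),
            ReLU(),
            Dropout(dropout, rng),
        )
        self.shortcut = None if c_in == c_out else Sequential(
            Conv1d(c_in, c_out, 1, rng=rng))


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    p = 1.0 / (1.0 + np.exp(-z))
    return float(loss), ((p - y) / z.size).astype(DTYPE)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self._scratch = None
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        # bias correction folded into the step size
        alpha = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        if self._scratch is None:
            self._scratch = [np.empty_like(p.data) for p in self.params]
        for p, m, v, buf in zip(self.params, self.m, self.v, self._scratch):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            np.multiply(p.grad, p.grad, out=buf)
            buf *= 1 - b2
            v += buf
            np.sqrt(v, out=buf)
            buf += self.eps * np.sqrt(1 - b2 ** self.t)
            np.divide(m, buf, out=buf)
            buf *= alpha
            p.data -= buf
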
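"""Minimal NumPy neural-network layers with exact analytic gradients.

Implements the pieces a 3D convolutional feature extractor needs — 3D
convolution (stride 1, 'same' padding), batch normalization, ReLU, 2x2x2 max
pooling, global average pooling, a fully connected layer — plus the Adam
optimizer.  Forward passes cache what the backward pass needs; gradients are
accumulated into ``.grads`` per layer and verified against finite differences
in the test suite.

Array layout is (batch, channels, z, y, x) throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: layers expose params(), grads(), forward(), backward()."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """3x3x3 convolution, stride 1, zero padding 1 (shape preserving)."""

    KSIZE = 3

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        k = self.KSIZE
        fan_in = c_in * k**3
        # He initialization, appropriate for ReLU nets
        self.weight = rng.standard_normal((c_out, c_in, k, k, k)) * np.sqrt(2.0 / fan_in)
        self.bias = np.zeros(c_out)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._cache: tuple | None = None

    def params(self):
        return [self.weight, self.bias]

    def grads(self):
        return [self.dweight, self.dbias]

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        """(B, C, D, H, W) -> (B, D*H*W, C*k^3) patch matrix, padding 1."""
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        # win: (B, C, D, H, W, k, k, k) -> (B, D, H, W, C, k, k, k)
        win = win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
        b = win.shape[0]
        return win.reshape(b, -1, x.shape[1] * k**3)

    def forward(self, x, train):
        b, c, d, h, w = x.shape
        cols = self._im2col(x, self.KSIZE)
        wmat = self.weight.reshape(self.weight.shape[0], -1)
        out = cols @ wmat.T + self.bias
        self._cache = (cols, (b, c, d, h, w))
        return out.transpose(0, 2, 1).reshape(b, -1, d, h, w)

    def backward(self, dy):
        cols, (b, c, d, h, w) = self._cache
        c_out = dy.shape[1]
        dyf = dy.reshape(b, c_out, -1).transpose(0, 2, 1)  # (B, S, C_out)
        wmat = self.weight.reshape(c_out, -1)
        self.dweight += np.einsum("bsc,bsk->ck", dyf, cols).reshape(self.weight.shape)
        self.dbias += dyf.sum(axis=(0, 1))
        # dx = conv(dy, W flipped, channels swapped); reuse im2col machinery
        wflip = self.weight[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        dycols = self._im2col(dy, self.KSIZE)
        dx = dycols @ wflip.reshape(c, -1).T
        return dx.transpose(0, 2, 1).reshape(b, c, d, h, w)


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (batch, z, y, x)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    @staticmethod
    def _bcast(v):
        return v[None, :, None, None, None]

    def forward(self, x, train):
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bcast(mean)) * self._bcast(ivar)
        self._cache = (xhat, ivar, x.shape, train)
        return self._bcast(self.gamma) * xhat + self._bcast(self.beta)

    def backward(self, dy):
        xhat, ivar, shape, train = self._cache
        axes = (0, 2, 3, 4)
        n = shape[0] * shape[2] * shape[3] * shape[4]
        self.dgamma += (dy * xhat).sum(axis=axes)
        self.dbeta += dy.sum(axis=axes)
        dxhat = dy * self._bcast(self.gamma)
        if not train:
            return dxhat * self._bcast(ivar)
        # standard batch-norm backward through the batch statistics
        t1 = n * dxhat
        t2 = dxhat.sum(axis=axes)
        t3 = xhat * (dxhat * xhat).sum(axis=axes)[None, :, None, None, None]
        return (self._bcast(ivar) / n) * (t1 - self._bcast(t2) - t3)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2; odd trailing planes are cropped."""

    def forward(self, x, train):
        b, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        xc = x[:, :, : 2 * d2, : 2 * h2, : 2 * w2]
        xr = xc.reshape(b, c, d2, 2, h2, 2, w2, 2)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(b, c, d2, h2, w2, 8)
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = (b, c, d, h, w)
        return xr.max(axis=-1)

    def backward(self, dy):
        b, c, d, h, w = self._in_shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        flat = np.zeros((b, c, d2, h2, w2, 8))
        np.put_along_axis(flat, self._argmax[..., None], dy[..., None], axis=-1)
        flat = flat.reshape(b, c, d2, h2, w2, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        dx = np.zeros((b, c, d, h, w))
        dx[:, :, : 2 * d2, : 2 * h2, : 2 * w2] = flat.reshape(b, c, 2 * d2, 2 * h2, 2 * w2)
        return dx


class GlobalAvgPool(Layer):
    """Collapse the spatial grid to one value per channel."""

    def forward(self, x, train):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy):
        b, c, d, h, w = self._in_shape
        return np.broadcast_to(dy[:, :, None, None, None], self._in_shape) / (d * h * w)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = rng.standard_normal((d_out, d_in)) * np.sqrt(1.0 / d_in)
        self.bias = np.zeros(d_out)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)

    def params(self):
        return [self.weight, self.bias]

    def grads(self):
        return [self.dweight, self.dbias]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.weight.T + self.bias

    def backward(self, dy):
        self.dweight += dy.T @ self._x
        self.dbias += dy.sum(axis=0)
        return dy @ self.weight


class Adam:
    """Adam with bias correction; operates in-place on a parameter list."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.grad_refs = grads
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for g in self.grad_refs:
            g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grad_refs, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max subtraction."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
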
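"""Layers with forward/backward passes.

Volumetric activations are channels-last ``(N, D, H, W, C)`` arrays: the
channel axis is contiguous, so every convolution offset reduces to one
contiguous slice copy plus one BLAS GEMM accumulated in place, which is
what keeps training practical on a single CPU.

Each layer caches what its backward pass needs during forward and exposes
``parameters()`` as a list of ``(param_array, grad_array)`` pairs that the
optimizer updates in place.  Forward passes accept ``train=`` so batch norm
and dropout can switch between training and inference behaviour.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import blas as _blas

__all__ = [
    "Layer", "Conv3d", "ConvTranspose3d", "Linear", "BatchNorm3d", "MaxPool3d",
    "Dropout", "ReLU", "LeakyReLU", "Sigmoid", "Flatten", "Concat", "Sequential",
]


def _colsum(a: np.ndarray) -> np.ndarray:
    """Column sums of a 2D array via BLAS matvec (numpy's axis-0 reduce is
    slow for narrow arrays)."""
    return np.ones(a.shape[0], dtype=a.dtype) @ a


def _gemm_acc(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> None:
    """c += a @ b without temporaries (C-order arrays, via the transposed
    Fortran view so BLAS makes no copies)."""
    gemm = _blas.sgemm if a.dtype == np.float32 else _blas.dgemm
    gemm(1.0, b.T, a.T, beta=1.0, c=c.T, overwrite_c=1)


class Layer:
    def parameters(self):
        return []

    def forward(self, x, train: bool = True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x, train: bool = True):
        return self.forward(x, train=train)

    def state_dict(self):
        return {}

    def load_state_dict(self, d):
        for k, v in d.items():
            getattr(self, k)[...] = v


def _he_init(rng, shape, fan_in, dtype):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


from ._kernels import col2im_acc, im2col as _im2col


class Conv3d(Layer):
    """3D convolution (cross-correlation), weight (k, k, k, Cin, Cout).

    Forward is one im2col unfold plus one GEMM; backward reuses the cached
    columns for the weight gradient and scatters the column gradient back
    with k^3 strided adds.
    """

    def __init__(self, c_in, c_out, kernel=3, stride=1, pad=0, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.k, self.s, self.p = kernel, stride, pad
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel**3
        self.W = _he_init(rng, (kernel, kernel, kernel, c_in, c_out), fan_in, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def state_dict(self):
        return {"W": self.W.copy(), "b": self.b.copy()}

    def _pad(self, x):
        p = self.p
        if not p:
            return np.ascontiguousarray(x)
        n, d, h, w, c = x.shape
        xp = np.zeros((n, d + 2 * p, h + 2 * p, w + 2 * p, c), dtype=x.dtype)
        xp[:, p:-p, p:-p, p:-p, :] = x
        return xp

    def forward(self, x, train: bool = True):
        if x.shape[-1] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[-1]}")
        xp = self._pad(x)
        self._in_spatial = x.shape[1:4]
        self._n = x.shape[0]
        if self.k == 1 and self.s == 1:
            self._cols = xp.reshape(-1, self.c_in)
            self._out_spatial = x.shape[1:4]
        else:
            self._cols, self._out_spatial = _im2col(xp, self.k, self.s)
        y = self._cols @ self.W.reshape(-1, self.c_out)
        y += self.b
        return y.reshape((self._n,) + self._out_spatial + (self.c_out,))

    def backward(self, dy):
        k, s, p = self.k, self.s, self.p
        do, ho, wo = self._out_spatial
        n = self._n
        dyc = np.ascontiguousarray(dy).reshape(-1, self.c_out)
        self.dW[...] = (self._cols.T @ dyc).reshape(self.dW.shape)
        self.db[...] = _colsum(dyc)
        dcols = dyc @ self.W.reshape(-1, self.c_out).T
        d, h, w = self._in_spatial
        if k == 1 and s == 1:
            dx = dcols.reshape(n, d, h, w, self.c_in)
            return dx
        dxp = np.zeros((n, d + 2 * p, h + 2 * p, w + 2 * p, self.c_in), dtype=dy.dtype)
        col2im_acc(dxp, dcols, (do, ho, wo), k, s)
        if p:
            return np.ascontiguousarray(dxp[:, p:-p, p:-p, p:-p, :])
        return dxp


class ConvTranspose3d(Layer):
    """3D transposed convolution, weight (k, k, k, Cin, Cout).

    Output spatial size is (D - 1) * stride + kernel - 2 * pad, the exact
    adjoint of Conv3d with the same hyperparameters.  Computed as
    zero-dilation of the input followed by a stride-1 convolution with the
    spatially flipped kernel, so it shares the fast im2col path.
    """

    def __init__(self, c_in, c_out, kernel=3, stride=1, pad=0, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.k, self.s, self.p = kernel, stride, pad
        if kernel - 1 - pad < 0:
            raise ValueError("pad must be <= kernel - 1")
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel**3
        self.W = _he_init(rng, (kernel, kernel, kernel, c_in, c_out), fan_in, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def state_dict(self):
        return {"W": self.W.copy(), "b": self.b.copy()}

    def _dilate_pad(self, x):
        s, q = self.s, self.k - 1 - self.p
        n, d, h, w, c = x.shape
        dd, hh, ww = ((dim - 1) * s + 1 + 2 * q for dim in (d, h, w))
        xd = np.zeros((n, dd, hh, ww, c), dtype=x.dtype)
        xd[:, q:dd - q:s, q:hh - q:s, q:ww - q:s, :] = x
        return xd

    def forward(self, x, train: bool = True):
        if x.shape[-1] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[-1]}")
        self._in_shape = x.shape
        xd = self._dilate_pad(x)
        self._cols, out_spatial = _im2col(xd, self.k, 1)
        wf = np.ascontiguousarray(self.W[::-1, ::-1, ::-1])
        y = self._cols @ wf.reshape(-1, self.c_out)
        y += self.b
        return y.reshape((x.shape[0],) + out_spatial + (self.c_out,))

    def backward(self, dy):
        k, s, q = self.k, self.s, self.k - 1 - self.p
        n, d, h, w, c = self._in_shape
        do, ho, wo = dy.shape[1:4]
        dyc = np.ascontiguousarray(dy).reshape(-1, self.c_out)
        dwf = (self._cols.T @ dyc).reshape(self.W.shape)
        self.dW[...] = dwf[::-1, ::-1, ::-1]
        self.db[...] = _colsum(dyc)
        wf = np.ascontiguousarray(self.W[::-1, ::-1, ::-1])
        dcols = dyc @ wf.reshape(-1, self.c_out).T
        dd, hh, ww = ((dim - 1) * s + 1 + 2 * q for dim in (d, h, w))
        dxd = np.zeros((n, dd, hh, ww, c), dtype=dy.dtype)
        col2im_acc(dxd, dcols, (do, ho, wo), k, 1)
        return np.ascontiguousarray(dxd[:, q:dd - q:s, q:hh - q:s, q:ww - q:s, :])


class FixedUpsample3d(Layer):
    """Fixed (non-trainable) transposed convolution with a triangle kernel:
    channelwise trilinear upsampling from 5^3 to 11^3, applied separably
    one axis at a time so it costs three small tensor contractions."""

    def __init__(self, n_in=5, n_out=11, dtype=np.float32):
        # interpolation matrix: input center d sits at output 2d+1; odd
        # outputs copy, even outputs average neighbours, edges clamp
        T = np.zeros((n_out, n_in), dtype=dtype)
        for t in range(n_out):
            pos = (t - 1) / 2.0
            lo = int(np.floor(pos))
            frac = pos - lo
            lo_c = min(max(lo, 0), n_in - 1)
            hi_c = min(max(lo + 1, 0), n_in - 1)
            T[t, lo_c] += 1.0 - frac
            T[t, hi_c] += frac
        self.T = T

    def _apply(self, x, T):
        for _ in range(3):
            # contract the leading spatial axis; it reappears last
            x = np.tensordot(x, T, axes=(1, 1))
        # x is now (N, C, D, H, W): restore channels-last
        return np.ascontiguousarray(x.transpose(0, 2, 3, 4, 1))

    def forward(self, x, train: bool = True):
        return self._apply(x, self.T)

    def backward(self, dy):
        return self._apply(dy, self.T.T)


class Linear(Layer):
    def __init__(self, n_in, n_out, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.W = _he_init(rng, (n_in, n_out), n_in, dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def state_dict(self):
        return {"W": self.W.copy(), "b": self.b.copy()}

    def forward(self, x, train: bool = True):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W) (channels-last)."""

    def __init__(self, c, momentum=0.1, eps=1e-5, dtype=np.float32):
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def parameters(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def state_dict(self):
        return {"gamma": self.gamma.copy(), "beta": self.beta.copy(),
                "running_mean": self.running_mean.copy(),
                "running_var": self.running_var.copy()}

    def forward(self, x, train: bool = True):
        shape = x.shape
        x2 = np.ascontiguousarray(x).reshape(-1, shape[-1])
        if train:
            m_inv = 1.0 / x2.shape[0]
            mean = _colsum(x2) * m_inv
            var = _colsum(x2 * x2) * m_inv - mean * mean
            np.maximum(var, 0.0, out=var)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mean
            self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        self._shape = shape
        self._std = np.sqrt(var + self.eps)
        inv = 1.0 / self._std
        self._x2, self._mean, self._inv = x2, mean, inv
        scale = self.gamma * inv
        shift = self.beta - mean * scale
        return (x2 * scale + shift).reshape(shape)

    def backward(self, dy):
        dy2 = np.ascontiguousarray(dy).reshape(-1, dy.shape[-1])
        m_inv = 1.0 / dy2.shape[0]
        xhat = (self._x2 - self._mean) * self._inv
        self.dgamma[...] = _colsum(dy2 * xhat)
        self.dbeta[...] = _colsum(dy2)
        dxhat = dy2 * self.gamma
        term = dxhat - _colsum(dxhat) * m_inv \
            - xhat * (_colsum(dxhat * xhat) * m_inv)
        return (term * self._inv).reshape(self._shape)


class MaxPool3d(Layer):
    """Non-overlapping max pooling (kernel = stride, floor mode)."""

    def __init__(self, kernel=2):
        self.k = kernel

    def forward(self, x, train: bool = True):
        k = self.k
        n, d, h, w, c = x.shape
        do, ho, wo = d // k, h // k, w // k
        self._in_shape = x.shape
        xc = x[:, :do * k, :ho * k, :wo * k, :]
        win = xc.reshape(n, do, k, ho, k, wo, k, c).transpose(0, 1, 3, 5, 2, 4, 6, 7)
        win = win.reshape(n, do, ho, wo, k**3, c)
        self._arg = win.argmax(axis=4)
        return win.max(axis=4)

    def backward(self, dy):
        k = self.k
        n, do, ho, wo, c = dy.shape
        flat = np.zeros((n, do, ho, wo, k**3, c), dtype=dy.dtype)
        np.put_along_axis(flat, self._arg[:, :, :, :, None, :], dy[:, :, :, :, None, :], axis=4)
        win = flat.reshape(n, do, ho, wo, k, k, k, c).transpose(0, 1, 4, 2, 5, 3, 6, 7)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, :do * k, :ho * k, :wo * k, :] = win.reshape(n, do * k, ho * k, wo * k, c)
        return dx


class Dropout(Layer):
    def __init__(self, p=0.5, rng=None):
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train: bool = True):
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.uniform(size=x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class ReLU(Layer):
    def forward(self, x, train: bool = True):
        self._pos = x > 0
        return x * self._pos

    def backward(self, dy):
        return dy * self._pos


class LeakyReLU(Layer):
    def __init__(self, alpha=0.2):
        self.alpha = alpha

    def forward(self, x, train: bool = True):
        self._pos = x > 0
        return np.where(self._pos, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._pos, dy, self.alpha * dy)


class Sigmoid(Layer):
    def forward(self, x, train: bool = True):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x, train: bool = True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Concat(Layer):
    """Concatenate along the channel (last) axis; backward splits the gradient."""

    def forward(self, xs, train: bool = True):
        self._sizes = [x.shape[-1] for x in xs]
        return np.concatenate(xs, axis=-1)

    def backward(self, dy):
        out, start = [], 0
        for sz in self._sizes:
            out.append(np.ascontiguousarray(dy[..., start:start + sz]))
            start += sz
        return out


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, train: bool = True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def state_dict(self):
        return {str(i): layer.state_dict() for i, layer in enumerate(self.layers)}

    def load_state_dict(self, d):
        for i, layer in enumerate(self.layers):
            layer.load_state_dict(d.get(str(i), {}))
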
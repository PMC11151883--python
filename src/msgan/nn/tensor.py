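"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the primitives the image-translation networks need:
strided convolution and transposed convolution (im2col based), instance
normalization, nearest-neighbour upsampling, channel concatenation, the
usual pointwise nonlinearities, and reductions.  Gradients are accumulated
through a topologically sorted tape rooted at the scalar loss.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

_DTYPE = np.float32


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph bookkeeping ------------------------------------------------

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=_DTYPE).copy()
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- operator sugar ---------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -other)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward):
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, _parents=tuple(parents) if req else (),
                  _backward=backward if req else None)


# -- elementwise ----------------------------------------------------------


def add(a, b):
    if not isinstance(b, Tensor):
        a = _as_tensor(a)
        out_data = a.data + b

        def backward(g):
            if a.requires_grad:
                a._accumulate(g)

        return _make(out_data, [a], backward)
    a = _as_tensor(a)
    if a.data.shape != b.data.shape:
        raise ValueError("add expects matching shapes")
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return _make(out_data, [a, b], backward)


def mul(a, b):
    a = _as_tensor(a)
    if not isinstance(b, Tensor):
        out_data = a.data * b

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * b)

        return _make(out_data, [a], backward)
    if a.data.shape != b.data.shape:
        raise ValueError("mul expects matching shapes")
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * b.data)
        if b.requires_grad:
            b._accumulate(g * a.data)

    return _make(out_data, [a, b], backward)


def tanh(x):
    y = np.tanh(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - y * y))

    return _make(y, [x], backward)


def sigmoid(x):
    y = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * y * (1.0 - y))

    return _make(y, [x], backward)


def relu(x):
    y = np.maximum(x.data, 0.0)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (x.data > 0))

    return _make(y, [x], backward)


def leaky_relu(x, slope: float = 0.2):
    y = np.where(x.data > 0, x.data, slope * x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * np.where(x.data > 0, 1.0, slope))

    return _make(y, [x], backward)


def softplus(x):
    # log(1 + e^x), numerically safe for large |x|
    y = np.logaddexp(0.0, x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g / (1.0 + np.exp(-x.data)))

    return _make(y, [x], backward)


def absolute(x):
    y = np.abs(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * np.sign(x.data))

    return _make(y, [x], backward)


# -- reductions and shape ops --------------------------------------------


def mean(x):
    y = np.array(x.data.mean(), dtype=_DTYPE)
    n = x.data.size

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.full_like(x.data, g / n))

    return _make(y, [x], backward)


def concat(tensors, axis: int = 1):
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _make(out_data, tensors, backward)


def upsample_nearest(x, factor: int = 2):
    """Nearest-neighbour 2x (or fxf) upsampling of an NCHW tensor."""
    f = int(factor)
    y = x.data.repeat(f, axis=2).repeat(f, axis=3)

    def backward(g):
        if x.requires_grad:
            n, c, h, w = x.data.shape
            x._accumulate(g.reshape(n, c, h, f, w, f).sum(axis=(3, 5)))

    return _make(y, [x], backward)


def dropout(x, rate: float, rng: np.random.Generator, training: bool = True):
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate).astype(_DTYPE) / (1.0 - rate)
    y = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return _make(y, [x], backward)


# -- im2col machinery -----------------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N,C,H,W) -> (k*k*C, N*Ho*Wo) patch matrix, offset-major.

    Row ordering is (i, j, c) so each kernel offset fills one contiguous
    block — the write pattern stays cache-friendly for large C.
    """
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    xt = x.transpose(1, 0, 2, 3)
    cols = np.empty((k, k, c, n, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[i, j] = xt[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
    return cols.reshape(k * k * c, n * ho * wo), ho, wo


def _col2im(cols: np.ndarray, n: int, c: int, h: int, w: int, k: int, stride: int,
            pad: int):
    """Scatter-add a (k*k*C, N*Ho*Wo) patch matrix back to (N,C,H,W)."""
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    cols6 = cols.reshape(k, k, c, n, ho, wo)
    out = np.zeros((c, n, hp, wp), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols6[i, j]
    out = out.transpose(1, 0, 2, 3)
    if pad:
        out = out[:, :, pad:hp - pad, pad:wp - pad]
    return out


def _flip_transpose_weight(weight: np.ndarray, c_out: int, c_in: int, k: int):
    """(C_out, k*k*C_in) -> (C_in, k*k*C_out) of the spatially flipped kernel."""
    w4 = weight.reshape(c_out, k, k, c_in)
    return np.ascontiguousarray(
        w4[:, ::-1, ::-1, :].transpose(3, 1, 2, 0)).reshape(c_in, k * k * c_out)


def conv2d(x, weight, bias, k: int, stride: int, pad: int):
    """Strided 2-D convolution (cross-correlation).

    weight is stored flat as (C_out, k*k*C_in) in (i, j, c) row order;
    bias as (C_out,).
    """
    n, c_in, h, w = x.data.shape
    c_out = weight.data.shape[0]
    cols, ho, wo = _im2col(x.data, k, stride, pad)
    out = np.matmul(weight.data, cols).reshape(c_out, n, ho, wo).transpose(1, 0, 2, 3)
    out = out + bias.data[None, :, None, None]

    def backward(g):
        gf = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(c_out, n * ho * wo)
        if weight.requires_grad:
            weight._accumulate(np.matmul(gf, cols.T))
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if stride == 1:
                # input grad = stride-1 convolution of g with the flipped,
                # transposed kernel; avoids a (k*k*C_in)-row scatter matrix
                w_t = _flip_transpose_weight(weight.data, c_out, c_in, k)
                gcols, _, _ = _im2col(g, k, 1, k - 1 - pad)
                dx = np.matmul(w_t, gcols).reshape(c_in, n, h, w).transpose(1, 0, 2, 3)
                x._accumulate(dx)
            else:
                dcols = np.matmul(weight.data.T, gf)
                x._accumulate(_col2im(dcols, n, c_in, h, w, k, stride, pad))

    return _make(out, [x, weight, bias], backward)


def conv_transpose2d(x, weight, bias, k: int, stride: int, pad: int):
    """Transposed convolution; the adjoint of conv2d with the same geometry.

    weight is stored flat as (C_in, k*k*C_out) in (i, j, c) row order;
    output spatial side is (H-1)*stride - 2*pad + k.
    """
    n, c_in, h, w = x.data.shape
    c_out = weight.data.shape[1] // (k * k)
    ho = (h - 1) * stride - 2 * pad + k
    wo = (w - 1) * stride - 2 * pad + k
    xf = np.ascontiguousarray(x.data.transpose(1, 0, 2, 3)).reshape(c_in, n * h * w)
    cols = np.matmul(weight.data.T, xf)  # (k*k*C_out, N*H*W)
    out = _col2im(cols, n, c_out, ho, wo, k, stride, pad)
    out = out + bias.data[None, :, None, None]

    def backward(g):
        gcols, _, _ = _im2col(g, k, stride, pad)  # (k*k*C_out, N*H*W)
        if weight.requires_grad:
            weight._accumulate(np.matmul(xf, gcols.T))
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxf = np.matmul(weight.data, gcols)
            x._accumulate(dxf.reshape(c_in, n, h, w).transpose(1, 0, 2, 3))

    return _make(out, [x, weight, bias], backward)


def instance_norm(x, gamma, beta, eps: float = 1e-5):
    """Per-sample, per-channel normalization over the spatial axes."""
    n, c, h, w = x.data.shape
    m = h * w
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=(2, 3), keepdims=True)
    ivstd = 1.0 / np.sqrt(var + eps)
    xhat = xc * ivstd
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = g * gamma.data[None, :, None, None]
            s1 = dxhat.sum(axis=(2, 3), keepdims=True)
            s2 = (dxhat * xhat).sum(axis=(2, 3), keepdims=True)
            x._accumulate(ivstd * (dxhat - s1 / m - xhat * s2 / m))

    return _make(out, [x, gamma, beta], backward)
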
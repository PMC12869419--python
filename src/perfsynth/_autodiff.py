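"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the synthesis network and its
physiology-informed losses need: elementwise arithmetic, reductions
(including min/max with subgradients), shape ops, pointwise
nonlinearities, and 2-D (transposed) convolution.  Gradients follow the
standard vector-Jacobian-product rules; convolutions are computed with
im2col/col2im so everything reduces to ``tensordot`` calls.

The engine is deliberately small: a :class:`Tensor` wraps an
``ndarray``, records its parents and a backward closure, and
``backward()`` runs a topological sweep.  Dtypes are preserved, so
float64 tensors give float64 gradients (used by the finite-difference
checks in the test-suite).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concatenate",
    "conv2d",
    "conv_transpose2d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple = ()

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- autograd ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, grad):
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(g)
            if other.requires_grad or other._parents:
                other._accumulate(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(g * other.data)
            if other.requires_grad or other._parents:
                other._accumulate(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        out = _node(self.data / other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(g / other.data)
            if other.requires_grad or other._parents:
                other._accumulate(-g * self.data / other.data**2)

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, p: float):
        out = _node(self.data**p, (self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    # -- shape ---------------------------------------------------------
    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bw
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def _minmax(self, fn, argcmp, axis, keepdims):
        val = fn(self.data, axis=axis, keepdims=True)
        out_data = val if keepdims else np.squeeze(val, axis=axis) if axis is not None else val.reshape(())
        out = _node(out_data, (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            else:
                g = g.reshape(val.shape)
            mask = argcmp(self.data, val)
            counts = mask.sum(axis=axis if axis is not None else None, keepdims=True)
            self._accumulate(np.broadcast_to(g, self.data.shape) * mask / counts)

        out._backward = bw
        return out

    def amin(self, axis=None, keepdims=False):
        return self._minmax(np.min, lambda d, v: d == v, axis, keepdims)

    def amax(self, axis=None, keepdims=False):
        return self._minmax(np.max, lambda d, v: d == v, axis, keepdims)

    # -- pointwise -----------------------------------------------------
    def abs(self):
        out = _node(np.abs(self.data), (self,))
        out._backward = lambda g: self._accumulate(g * np.sign(self.data))
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def exp(self):
        out = _node(np.exp(self.data), (self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def tanh(self):
        out = _node(np.tanh(self.data), (self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - out.data**2))
        return out

    def sigmoid(self):
        out = _node(1.0 / (1.0 + np.exp(-self.data)), (self,))
        out._backward = lambda g: self._accumulate(g * out.data * (1.0 - out.data))
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = _node(np.where(self.data > 0, self.data, slope * self.data), (self,))
        out._backward = lambda g: self._accumulate(
            g * np.where(self.data > 0, 1.0, slope)
        )
        return out

    def clamp(self, lo: float, hi: float):
        out = _node(np.clip(self.data, lo, hi), (self,))
        out._backward = lambda g: self._accumulate(
            g * ((self.data > lo) & (self.data < hi))
        )
        return out


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents) -> Tensor:
    """Create an interior tape node; prune parents that need no grad."""
    track = tuple(p for p in parents if p.requires_grad or p._parents)
    out = Tensor(data)
    out._parents = track
    return out


def concatenate(tensors, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])

    out._backward = bw
    return out


# ---------------------------------------------------------------------
# 2-D convolution primitives (NCHW layout, square kernel/stride)
# ---------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Return overlapping patches (N, C, Ho, Wo, k, k)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    return windows[:, :, ::stride, ::stride, :, :]


def _col2im(cols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int):
    """Scatter-add patches back; inverse (adjoint) of :func:`_im2col`."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho, wo = cols.shape[2], cols.shape[3]
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for p in range(k):
        for q in range(k):
            out[:, :, p : p + stride * ho : stride, q : q + stride * wo : stride] += (
                cols[:, :, :, :, p, q]
            )
    return out[:, :, pad : pad + h, pad : pad + w]


def _conv_fwd(x, w, stride, pad):
    cols = _im2col(x, w.shape[2], stride, pad)
    y = np.tensordot(cols, w, axes=([1, 4, 5], [1, 2, 3]))  # (N,Ho,Wo,O)
    return np.ascontiguousarray(y.transpose(0, 3, 1, 2)), cols


def _conv_gw(gy, cols):
    # gy: (N,O,Ho,Wo); cols: (N,C,Ho,Wo,k,k) -> (O,C,k,k)
    return np.tensordot(gy, cols, axes=([0, 2, 3], [0, 2, 3]))


def _conv_gx(gy, w, x_shape, stride, pad):
    # dcols[n,c,i,j,p,q] = sum_o gy[n,o,i,j] w[o,c,p,q]
    dcols = np.tensordot(gy.transpose(0, 2, 3, 1), w, axes=([3], [0]))
    dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N,C,Ho,Wo,k,k)
    return _col2im(dcols, x_shape, w.shape[2], stride, pad)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """Cross-correlation of `x` (N,C,H,W) with `w` (O,C,k,k)."""
    x, w = _wrap(x), _wrap(w)
    y, cols = _conv_fwd(x.data, w.data, stride, pad)
    if b is not None:
        y = y + b.data[None, :, None, None]
        out = _node(y, (x, w, b))
    else:
        out = _node(y, (x, w))

    def bw(g):
        if x.requires_grad or x._parents:
            x._accumulate(_conv_gx(g, w.data, x.data.shape, stride, pad))
        if w.requires_grad or w._parents:
            w._accumulate(_conv_gw(g, cols))
        if b is not None and (b.requires_grad or b._parents):
            b._accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 1, pad: int = 0) -> Tensor:
    """Transposed convolution; `w` has layout (C_in, C_out, k, k).

    Output spatial side = (H - 1) * stride - 2 * pad + k, i.e. the adjoint
    of a stride-`stride` convolution that would map that output back to H.
    """
    x, w = _wrap(x), _wrap(w)
    n, cin, h, _ = x.data.shape
    k = w.data.shape[2]
    hout = (h - 1) * stride - 2 * pad + k
    y_shape = (n, w.data.shape[1], hout, hout)
    y = _conv_gx(x.data, w.data, y_shape, stride, pad)
    if b is not None:
        y = y + b.data[None, :, None, None]
        out = _node(y, (x, w, b))
    else:
        out = _node(y, (x, w))

    def bw(g):
        if x.requires_grad or x._parents:
            gx, _ = _conv_fwd(g, w.data, stride, pad)
            x._accumulate(gx)
        if w.requires_grad or w._parents:
            cols = _im2col(g, k, stride, pad)
            w._accumulate(_conv_gw(x.data, cols))
        if b is not None and (b.requires_grad or b._parents):
            b._accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out
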
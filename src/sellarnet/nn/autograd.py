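"""Compact reverse-mode automatic differentiation over numpy arrays.

This is the numerical core the network and losses are built on: a
:class:`Tensor` wrapping a float32 ndarray, a small set of differentiable
primitives (elementwise arithmetic, matmul, reductions, 2-D convolution via
im2col, batch normalization, bilinear upsampling, softmax), and a
topological-order backward pass.  It is deliberately minimal — only the
operations the model and its losses need — and favours vectorized numpy so a
small network trains in minutes on one CPU core.

Gradient correctness is validated against central finite differences in the
test suite for every primitive with a hand-written backward rule.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "no_grad",
    "concatenate",
    "conv2d",
    "batch_norm2d",
    "upsample_bilinear",
    "softmax",
    "where_const",
]

_grad_enabled: bool = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (used for evaluation-mode forward passes)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd machinery ---------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for a many-layer network
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not (p.requires_grad or p._backward is not None):
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    def zero_grad(self) -> None:
        self.grad = None


def _make(data: np.ndarray, parents: Iterable[Tensor], backward) -> Tensor:
    parents = tuple(parents)
    track = _grad_enabled and any(
        p.requires_grad or p._backward is not None for p in parents
    )
    out = Tensor(data)
    if track:
        out._parents = parents
        out._backward = backward
    return out


# -- elementwise and reduction primitives -------------------------------------

def _add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data
    return _make(data, (a, b), lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def _mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data
    return _make(
        data,
        (a, b),
        lambda g: (_unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)),
    )


def _sub(a: Tensor, b: Tensor) -> Tensor:
    data = a.data - b.data
    return _make(data, (a, b), lambda g: (_unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)))


def _div(a: Tensor, b: Tensor) -> Tensor:
    data = a.data / b.data
    def backward(g):
        return (
            _unbroadcast(g / b.data, a.shape),
            _unbroadcast(-g * a.data / (b.data * b.data), b.shape),
        )
    return _make(data, (a, b), backward)


def _coerce(other) -> Tensor:
    return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float32))


Tensor.__add__ = lambda self, o: _add(self, _coerce(o))
Tensor.__radd__ = lambda self, o: _add(_coerce(o), self)
Tensor.__mul__ = lambda self, o: _mul(self, _coerce(o))
Tensor.__rmul__ = lambda self, o: _mul(_coerce(o), self)
Tensor.__sub__ = lambda self, o: _sub(self, _coerce(o))
Tensor.__rsub__ = lambda self, o: _sub(_coerce(o), self)
Tensor.__truediv__ = lambda self, o: _div(self, _coerce(o))
Tensor.__rtruediv__ = lambda self, o: _div(_coerce(o), self)
Tensor.__neg__ = lambda self: _mul(self, Tensor(np.float32(-1.0)))


def _pow_const(a: Tensor, exponent: float) -> Tensor:
    data = a.data ** exponent
    return _make(data, (a,), lambda g: (g * exponent * a.data ** (exponent - 1),))


Tensor.__pow__ = _pow_const


def _matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data
    return _make(data, (a, b), lambda g: (g @ b.data.T, a.data.T @ g))


Tensor.__matmul__ = _matmul


def exp(a: Tensor) -> Tensor:
    data = np.exp(a.data)
    return _make(data, (a,), lambda g: (g * data,))


def log(a: Tensor) -> Tensor:
    return _make(np.log(a.data), (a,), lambda g: (g / a.data,))


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return _make(a.data * mask, (a,), lambda g: (g * mask,))


def sigmoid(a: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-a.data))
    return _make(data, (a,), lambda g: (g * data * (1.0 - data),))


def abs_(a: Tensor) -> Tensor:
    sign = np.sign(a.data)
    return _make(np.abs(a.data), (a,), lambda g: (g * sign,))


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)
    return _make(data, (a,), lambda g: (g * mask,))


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).astype(np.float32),)

    return _make(data, (a,), backward)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return sum_(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


Tensor.sum = sum_
Tensor.mean = mean


def reshape(a: Tensor, shape) -> Tensor:
    return _make(a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),))


Tensor.reshape = reshape


def where_const(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Elementwise select with a *constant* boolean mask (no grad w.r.t. mask)."""
    mask = np.asarray(mask, dtype=bool)
    data = np.where(mask, a.data, b.data)

    def backward(g):
        return (
            _unbroadcast(g * mask, a.shape),
            _unbroadcast(g * ~mask, b.shape),
        )

    return _make(data, (a, b), backward)


def concatenate(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(data, tuple(tensors), backward)


def softmax(a: Tensor, axis: int = 1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        return (y * (g - (g * y).sum(axis=axis, keepdims=True)),)

    return _make(y, (a,), backward)


# -- convolution ---------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW input, OIHW weights."""
    n, c, h, wd = x.shape
    o, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, weight expects {ci}")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    ho = (h + 2 * p - kh) // s + 1
    wo = (wd + 2 * p - kw) // s + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * kh * kw
    )
    wmat = w.data.reshape(o, c * kh * kw)
    out = (cols @ wmat.T).reshape(n, ho, wo, o).transpose(0, 3, 1, 2)

    def backward(g):
        gf = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, o)
        dw = (gf.T @ cols).reshape(o, c, kh, kw)
        dcols = (gf @ wmat).reshape(n, ho, wo, c, kh, kw)
        dxp = np.zeros((n, c, h + 2 * p, wd + 2 * p), dtype=np.float32)
        for ki in range(kh):
            for kj in range(kw):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += (
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
                )
        dx = dxp[:, :, p : p + h, p : p + wd] if p else dxp
        return dx, dw

    return _make(out, (x, w), backward)


# -- batch normalization -------------------------------------------------------

def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W); updates running stats in place."""
    axes = (0, 2, 3)
    gshape = (1, -1, 1, 1)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(gshape)) * inv_std.reshape(gshape)
    out = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)

    m = x.shape[0] * x.shape[2] * x.shape[3]

    def backward(g):
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        gs = gamma.data.reshape(gshape) * inv_std.reshape(gshape)
        if training:
            dx = gs * (
                g
                - dbeta.reshape(gshape) / m
                - xhat * dgamma.reshape(gshape) / m
            )
        else:
            dx = gs * g
        return dx.astype(np.float32), dgamma, dbeta

    return _make(out, (x, gamma, beta), backward)


# -- bilinear upsampling -------------------------------------------------------

_interp_cache: dict[tuple[int, int], np.ndarray] = {}


def _interp_matrix(size: int, factor: int) -> np.ndarray:
    """(size*factor, size) linear-interpolation matrix, half-pixel centers."""
    key = (size, factor)
    if key not in _interp_cache:
        out = np.arange(size * factor)
        src = (out + 0.5) / factor - 0.5
        fl = np.floor(src)
        w = (src - fl).astype(np.float32)
        i0 = np.clip(fl, 0, size - 1).astype(np.intp)
        i1 = np.clip(fl + 1, 0, size - 1).astype(np.intp)
        mat = np.zeros((size * factor, size), dtype=np.float32)
        np.add.at(mat, (out, i0), 1.0 - w)
        np.add.at(mat, (out, i1), w)
        _interp_cache[key] = mat
    return _interp_cache[key]


def _upsample_axis(x: Tensor, axis: int, factor: int) -> Tensor:
    mat = _interp_matrix(x.shape[axis], factor)
    data = np.moveaxis(np.tensordot(x.data, mat, axes=([axis], [1])), -1, axis)

    def backward(g):
        dx = np.tensordot(g, mat, axes=([axis], [0]))
        return (np.ascontiguousarray(np.moveaxis(dx, -1, axis)),)

    return _make(data, (x,), backward)


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    """Bilinear upsampling of an NCHW map by an integer factor (half-pixel centers)."""
    if factor == 1:
        return x
    return _upsample_axis(_upsample_axis(x, 2, factor), 3, factor)
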
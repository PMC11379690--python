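"""Minimal reverse-mode automatic differentiation over numpy arrays.

Everything runs in float32. A :class:`Tensor` wraps a numpy array and, when
gradients are enabled and at least one input requires a gradient, records a
closure that propagates the output gradient to its parents. ``backward()`` on
a scalar loss runs the recorded closures in reverse topological order.

The op set is deliberately small: exactly what the encoder, heads and the two
self-supervised losses need (elementwise arithmetic with broadcasting, matmul,
1-D convolution, relu/exp/log/sqrt/softplus, reductions, reshaping, row
gather). Each primitive's backward is verified against central finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were expanded
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype != np.float64:  # float32 by default, float64 preserved
            data = data.astype(np.float32, copy=False)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._prev: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; recursion depth can exceed limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return add(self, -other)
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, exponent):
        return power(self, exponent)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    @property
    def T(self):
        return transpose(self, None)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(parents)
        out._backward = backward
    return out


# -- elementwise arithmetic ------------------------------------------------

def add(a, b) -> Tensor:
    if isinstance(a, (int, float)):
        a, b = b, a
    if isinstance(b, (int, float)):  # python scalars never change the dtype
        a = _wrap(a)
        c = float(b)
        out_data = a.data + c

        def backward():
            if a.requires_grad:
                a._accum(out.grad)

        out = _make(out_data, (a,), backward)
        return out
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward():
        g = out.grad
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    out = _make(out_data, (a, b), backward)
    return out


def mul(a, b) -> Tensor:
    if isinstance(a, (int, float)):
        a, b = b, a
    if isinstance(b, (int, float)):
        a = _wrap(a)
        c = float(b)
        out_data = a.data * c

        def backward():
            if a.requires_grad:
                a._accum(out.grad * c)

        out = _make(out_data, (a,), backward)
        return out
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward():
        g = out.grad
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    out = _make(out_data, (a, b), backward)
    return out


def div(a, b) -> Tensor:
    if isinstance(b, (int, float)):
        return mul(a, 1.0 / float(b))
    a, b = _wrap(a), _wrap(b)
    out_data = a.data / b.data

    def backward():
        g = out.grad
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    out = _make(out_data, (a, b), backward)
    return out


def power(a, exponent: float) -> Tensor:
    a = _wrap(a)
    e = float(exponent)
    out_data = a.data ** e

    def backward():
        if a.requires_grad:
            a._accum(out.grad * e * a.data ** (e - 1.0))

    out = _make(out_data, (a,), backward)
    return out


# -- nonlinearities --------------------------------------------------------

def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward():
        if a.requires_grad:
            a._accum(out.grad * mask)

    out = _make(out_data, (a,), backward)
    return out


def exp(a) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)

    def backward():
        if a.requires_grad:
            a._accum(out.grad * out_data)

    out = _make(out_data, (a,), backward)
    return out


def log(a) -> Tensor:
    a = _wrap(a)
    out_data = np.log(a.data)

    def backward():
        if a.requires_grad:
            a._accum(out.grad / a.data)

    out = _make(out_data, (a,), backward)
    return out


def sqrt(a) -> Tensor:
    a = _wrap(a)
    out_data = np.sqrt(a.data)

    def backward():
        if a.requires_grad:
            a._accum(out.grad * 0.5 / out_data)

    out = _make(out_data, (a,), backward)
    return out


def softplus(a) -> Tensor:
    """Numerically stable log(1 + exp(a)); gradient is the logistic sigmoid."""
    a = _wrap(a)
    x = a.data
    out_data = np.where(x > 0, x + np.log1p(np.exp(-np.abs(x))),
                        np.log1p(np.exp(-np.abs(x)))).astype(x.dtype)

    def backward():
        if a.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-x))
            a._accum(out.grad * sig)

    out = _make(out_data, (a,), backward)
    return out


# -- reductions ------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward():
        if not a.requires_grad:
            return
        g = out.grad
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.data.ndim for ax in axes)
            shape = [1 if i in axes else s for i, s in enumerate(a.data.shape)]
            g = g.reshape(shape)
        a._accum(np.broadcast_to(g, a.data.shape))

    out = _make(out_data, (a,), backward)
    return out


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


# -- shape ops -------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    out_data = a.data.reshape(shape)

    def backward():
        if a.requires_grad:
            a._accum(out.grad.reshape(a.data.shape))

    out = _make(out_data, (a,), backward)
    return out


def transpose(a, axes=None) -> Tensor:
    a = _wrap(a)
    out_data = np.transpose(a.data, axes)

    def backward():
        if a.requires_grad:
            inv = None if axes is None else np.argsort(axes)
            a._accum(np.transpose(out.grad, inv))

    out = _make(out_data, (a,), backward)
    return out


def concat(tensors: Iterable, axis: int = 0) -> Tensor:
    ts = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out_data.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out = _make(out_data, ts, backward)
    return out


# -- linear algebra --------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward():
        g = out.grad
        if a.requires_grad:
            a._accum(g @ b.data.T if b.data.ndim == 2 else np.outer(g, b.data))
        if b.requires_grad:
            b._accum(a.data.T @ g)

    out = _make(out_data, (a, b), backward)
    return out


def gather_rows(a, idx) -> Tensor:
    """out[i] = a[i, idx[i]] for a 2-D tensor; used by the softmax CE loss."""
    a = _wrap(a)
    idx = np.asarray(idx, dtype=np.int64)
    rows = np.arange(a.data.shape[0])
    out_data = a.data[rows, idx]

    def backward():
        if a.requires_grad:
            g = np.zeros_like(a.data)
            np.add.at(g, (rows, idx), out.grad)
            a._accum(g)

    out = _make(out_data, (a,), backward)
    return out


# -- 1-D convolution -------------------------------------------------------

def _im2col(xp: np.ndarray, K: int, stride: int, L_out: int) -> np.ndarray:
    """Strided view (N, C, L_out, K) over padded input (read-only)."""
    N, C, _ = xp.shape
    s0, s1, s2 = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, shape=(N, C, L_out, K), strides=(s0, s1, s2 * stride, s2),
        writeable=False)


def conv1d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation along the last axis.

    x: (N, C_in, L), w: (C_out, C_in, K), b: (C_out,) or None.
    """
    x, w = _wrap(x), _wrap(w)
    parents = [x, w]
    if b is not None:
        b = _wrap(b)
        parents.append(b)
    N, C_in, L = x.data.shape
    C_out, _, K = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    L_out = (L + 2 * padding - K) // stride + 1
    cols = _im2col(xp, K, stride, L_out)
    out_data = np.tensordot(w.data, cols, axes=([1, 2], [1, 3])).transpose(1, 0, 2)
    if b is not None:
        out_data = out_data + b.data[None, :, None]

    def backward():
        g = out.grad  # (N, C_out, L_out)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if w.requires_grad:
            # (C_out, C_in, K) = sum over (N, L_out)
            w._accum(np.tensordot(g, cols, axes=([0, 2], [0, 2])))
        if x.requires_grad:
            g_cols = np.einsum("nol,ock->nclk", g, w.data)
            dxp = np.zeros_like(xp)
            for k in range(K):
                dxp[:, :, k:k + stride * L_out:stride] += g_cols[:, :, :, k]
            x._accum(dxp[:, :, padding:padding + L] if padding else dxp)

    out = _make(out_data, parents, backward)
    return out


def logsumexp_rows(a) -> Tensor:
    """Row-wise logsumexp of a 2-D tensor, stabilized with a detached max."""
    a = _wrap(a)
    m = a.data.max(axis=1, keepdims=True)  # constant w.r.t. the graph
    shifted = add(a, Tensor(-m))
    return add(log(tsum(exp(shifted), axis=1)), Tensor(m[:, 0]))
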
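"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine is deliberately small: dense float64 tensors, a handful of
operations (enough for attention over graph edges, 1-D convolution and
fully-connected layers), and topological-order backpropagation.  Segment
operations (``segment_sum``, ``segment_max``) operate on row groups defined
by an integer segment-id vector, which is how batched molecular graphs are
pooled and how attention softmax is normalised per neighbourhood.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # copy: the incoming buffer may be shared with another consumer
            self.grad = np.array(grad, dtype=np.float64)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward, requires) -> Tensor:
    return Tensor(data, requires_grad=requires, parents=parents, backward=backward)


# -- elementwise ----------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data
    req = a.requires_grad or b.requires_grad

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward, req)


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data
    req = a.requires_grad or b.requires_grad

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward, req)


def power(a, exponent: float) -> Tensor:
    a = astensor(a)
    out_data = a.data**exponent

    def backward(g):
        a._accumulate(g * exponent * a.data ** (exponent - 1.0))

    return _make(out_data, (a,), backward, a.requires_grad)


def exp(a) -> Tensor:
    a = astensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return _make(out_data, (a,), backward, a.requires_grad)


def log(a) -> Tensor:
    a = astensor(a)
    out_data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(out_data, (a,), backward, a.requires_grad)


def relu(a) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        a._accumulate(g * mask)

    return _make(out_data, (a,), backward, a.requires_grad)


def sigmoid(a) -> Tensor:
    a = astensor(a)
    out_data = 0.5 * (1.0 + np.tanh(0.5 * a.data))  # numerically stable

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward, a.requires_grad)


# -- shape / reduction -----------------------------------------------------


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(out_data, (a,), backward, a.requires_grad)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            grad = np.broadcast_to(g, a.data.shape)
        else:
            g_exp = g if keepdims else np.expand_dims(g, axis)
            grad = np.broadcast_to(g_exp, a.data.shape)
        a._accumulate(grad.astype(np.float64))

    return _make(out_data, (a,), backward, a.requires_grad)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    req = any(t.requires_grad for t in ts)

    def backward(g):
        offset = 0
        for t, size in zip(ts, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(offset, offset + size)
                t._accumulate(g[tuple(sl)])
            offset += size

    return _make(out_data, ts, backward, req)


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data @ b.data
    req = a.requires_grad or b.requires_grad

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(out_data, (a, b), backward, req)


# -- gather / segment ops --------------------------------------------------


def gather_rows(a, index: np.ndarray) -> Tensor:
    """Select rows ``a[index]`` (used for edge endpoints and embeddings)."""
    a = astensor(a)
    index = np.asarray(index, dtype=np.intp)
    out_data = a.data[index]

    def backward(g):
        grad = np.zeros_like(a.data)
        np.add.at(grad, index, g)
        a._accumulate(grad)

    return _make(out_data, (a,), backward, a.requires_grad)


def segment_sum(a, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``num_segments`` buckets."""
    a = astensor(a)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((num_segments,) + a.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, segment_ids, a.data)

    def backward(g):
        a._accumulate(g[segment_ids])

    return _make(out_data, (a,), backward, a.requires_grad)


def segment_max(a, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Columnwise max of rows within each segment.

    Gradient is split equally among tied maxima (a valid subgradient).
    Every segment id in ``range(num_segments)`` must own at least one row.
    """
    a = astensor(a)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.full((num_segments,) + a.data.shape[1:], -np.inf)
    np.maximum.at(out_data, segment_ids, a.data)

    def backward(g):
        is_max = (a.data == out_data[segment_ids]).astype(np.float64)
        counts = np.zeros_like(out_data)
        np.add.at(counts, segment_ids, is_max)
        a._accumulate(is_max * (g / counts)[segment_ids])

    return _make(out_data, (a,), backward, a.requires_grad)


def segment_softmax(scores, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a score vector within each segment (shape (E,) → (E,)).

    Max-shifting for numerical stability uses detached values, which leaves
    the gradient unchanged (softmax is shift-invariant).
    """
    scores = astensor(scores)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    shift = np.full((num_segments,), -np.inf)
    np.maximum.at(shift, segment_ids, scores.data)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    shifted = add(scores, Tensor(-shift[segment_ids]))
    e = exp(shifted)
    denom = segment_sum(reshape(e, (-1, 1)), segment_ids, num_segments)
    denom_per_edge = gather_rows(denom, segment_ids)
    return mul(e, power(reshape(denom_per_edge, (-1,)), -1.0))


# -- convolution / pooling -------------------------------------------------


def conv1d(x, w, b) -> Tensor:
    """Valid 1-D convolution. x: (B, L, Cin); w: (Cout, K, Cin); b: (Cout,)."""
    x, w, b = astensor(x), astensor(w), astensor(b)
    B, L, Cin = x.data.shape
    Cout, K, _ = w.data.shape
    if w.data.shape[2] != Cin:
        raise ValueError(f"conv1d channel mismatch: input {Cin}, kernel {w.data.shape[2]}")
    if L < K:
        raise ValueError(f"conv1d sequence length {L} shorter than kernel {K}")
    Lout = L - K + 1
    cols = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=1)  # (B, Lout, Cin, K)
    cols = cols.transpose(0, 1, 3, 2).reshape(B * Lout, K * Cin)
    w2 = w.data.reshape(Cout, K * Cin)
    out_data = (cols @ w2.T).reshape(B, Lout, Cout) + b.data
    req = x.requires_grad or w.requires_grad or b.requires_grad

    def backward(g):
        g2 = g.reshape(B * Lout, Cout)
        if b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        if w.requires_grad:
            w._accumulate((g2.T @ cols).reshape(Cout, K, Cin))
        if x.requires_grad:
            gcols = (g2 @ w2).reshape(B, Lout, K, Cin)
            gx = np.zeros_like(x.data)
            for k in range(K):
                gx[:, k : k + Lout, :] += gcols[:, :, k, :]
            x._accumulate(gx)

    return _make(out_data, (x, w, b), backward, req)


def maxpool1d(x, window: int) -> Tensor:
    """Non-overlapping max pooling along axis 1. x: (B, L, C); a tail
    shorter than ``window`` is dropped."""
    x = astensor(x)
    B, L, C = x.data.shape
    Lout = L // window
    if Lout < 1:
        raise ValueError(f"maxpool1d: length {L} shorter than window {window}")
    Ltrim = Lout * window
    blocks = x.data[:, :Ltrim].reshape(B, Lout, window, C)
    arg = blocks.argmax(axis=2)  # (B, Lout, C)
    out_data = np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(g):
        gblocks = np.zeros_like(blocks)
        np.put_along_axis(gblocks, arg[:, :, None, :], g[:, :, None, :], axis=2)
        gx = np.zeros_like(x.data)
        gx[:, :Ltrim] = gblocks.reshape(B, Ltrim, C)
        x._accumulate(gx)

    return _make(out_data, (x,), backward, x.requires_grad)
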
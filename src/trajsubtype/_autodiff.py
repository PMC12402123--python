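"""Minimal reverse-mode automatic differentiation on numpy arrays.

The guided temporal VAE needs gradients through dense layers, an LSTM
recurrence, gathers over (patient, anchor, target-visit) index triples and
masked likelihood sums.  This module provides exactly that: a ``Tensor``
wrapping an ``ndarray`` with a recorded backward closure, plus the small set
of differentiable primitives the model uses.  Shapes follow numpy broadcasting
rules; gradients of broadcast operands are summed back to the operand shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (T * anchors)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- constructors for op results --------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._result(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accumulate(-g)

        return Tensor._result(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._result(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / b.data**2, b.shape))

        return Tensor._result(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)

        return Tensor._result(a.data @ b.data, (a, b), bwd)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accumulate(g * out_data)

        return Tensor._result(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accumulate(g / a.data)

        return Tensor._result(np.log(a.data), (a,), bwd)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bwd(g):
            a._accumulate(g * 0.5 / out_data)

        return Tensor._result(out_data, (a,), bwd)

    def square(self):
        a = self

        def bwd(g):
            a._accumulate(g * 2.0 * a.data)

        return Tensor._result(a.data**2, (a,), bwd)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bwd(g):
            a._accumulate(g * (1.0 - out_data**2))

        return Tensor._result(out_data, (a,), bwd)

    def sigmoid(self):
        a = self
        out_data = 0.5 * (1.0 + np.tanh(0.5 * a.data))  # numerically stable

        def bwd(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (a,), bwd)

    def softplus(self):
        a = self
        # log(1+exp(x)) computed stably
        out_data = np.logaddexp(0.0, a.data)
        sig = 0.5 * (1.0 + np.tanh(0.5 * a.data))

        def bwd(g):
            a._accumulate(g * sig)

        return Tensor._result(out_data, (a,), bwd)

    # -- reductions and shape ops ------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.shape).copy())

        return Tensor._result(out_data, (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        a = self
        orig = a.shape

        def bwd(g):
            a._accumulate(g.reshape(orig))

        return Tensor._result(a.data.reshape(*shape), (a,), bwd)

    def __getitem__(self, idx):
        """Slice or fancy-index; backward scatter-adds into the source."""
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor._result(a.data[idx], (a,), bwd)

    def log_softmax(self, axis=-1):
        """Stable log-softmax along ``axis``."""
        a = self
        m = a.data.max(axis=axis, keepdims=True)
        shifted = a - Tensor(m)
        lse = shifted.exp().sum(axis=axis, keepdims=True).log()
        return shifted - lse


def concat(tensors, axis: int = -1) -> Tensor:
    """Differentiable concatenation along ``axis``."""
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._result(data, tuple(tensors), bwd)


def stack_rows(tensors) -> Tensor:
    """Stack equal-shape tensors along a new leading axis."""
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=0)

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(g[i])

    return Tensor._result(data, tuple(tensors), bwd)
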
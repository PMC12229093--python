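"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine implements exactly the operations the package's models need:
broadcast arithmetic, (batched) matmul, elementwise nonlinearities,
reductions, reshaping, fancy indexing and concatenation.  Gradients are
accumulated by a topological sweep over the recorded graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "softmax", "log_softmax", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        # Never mutate an incoming gradient in place: it may be a view of (or
        # the same buffer as) a gradient routed to another node.
        if self.grad is None:
            if isinstance(g, np.ndarray) and g.dtype == self.data.dtype and g.shape == self.data.shape:
                self.grad = g
            else:
                self.grad = np.broadcast_to(
                    np.asarray(g, dtype=self.data.dtype), self.data.shape).copy()
        else:
            self.grad = self.grad + g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(grad)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _wrap_like(self, other) -> "Tensor":
        """Wrap, coercing python scalars to this tensor's dtype so float32
        graphs are not silently promoted to float64."""
        if isinstance(other, Tensor):
            return other
        if isinstance(other, (int, float)) and np.issubdtype(self.data.dtype, np.floating):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(other)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        a, b = self, self._wrap_like(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._result(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return self._result(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-self._wrap_like(other))

    def __rsub__(self, other):
        return self._wrap_like(other) + (-self)

    def __mul__(self, other):
        a, b = self, self._wrap_like(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._result(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, self._wrap_like(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return self._result(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._wrap_like(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def backward(g):
            a._accum(g * e * a.data ** (e - 1.0))

        return self._result(a.data ** e, (a,), backward)

    def __matmul__(self, other):
        a, b = self, self._wrap(other)

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return self._result(a.data @ b.data, (a, b), backward)

    # -- elementwise -------------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return self._result(out_data, (a,), lambda g: a._accum(g * out_data))

    def log(self):
        a = self
        return self._result(np.log(a.data), (a,), lambda g: a._accum(g / a.data))

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return self._result(out_data, (a,), lambda g: a._accum(g * (1.0 - out_data ** 2)))

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accum(g * mask)

        return self._result(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))
        return self._result(out_data, (a,), lambda g: a._accum(g * out_data * (1.0 - out_data)))

    def sqrt(self):
        return self ** 0.5

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return self._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            denom = self.data.size
        else:
            denom = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(denom)

    # -- shape -------------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            a._accum(g.reshape(a.shape))

        return self._result(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(inv))

        return self._result(a.data.transpose(axes), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return self._result(a.data[idx], (a,), backward)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._result(data, tensors, backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # subtracting the detached row max leaves value and gradient unchanged
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


_GRAD_ENABLED = True


class no_grad:
    """Context manager suppressing graph construction (inference paths)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False
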
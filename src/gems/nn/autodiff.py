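"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for the graph network: broadcast arithmetic, matrix
products, leaky-ReLU family nonlinearities, row gather/scatter (the message
passing primitives) and reductions. Gradients are accumulated by a
topological backward sweep; the engine is deliberately eager and small so
the finite-difference gradient check in the test suite can validate it end
to end.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (undo NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False) -> None:
        self.data = np.asarray(data, dtype=float)
        self.grad: Array | None = None
        self.requires_grad = requires_grad
        self._parents: tuple["Tensor", ...] = ()
        self._backward: Callable[[Array], None] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(value) -> "Tensor":
        return value if isinstance(value, Tensor) else Tensor(value)

    def _make(self, data: Array, parents: tuple["Tensor", ...],
              backward: Callable[[Array], None]) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, grad: Array) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad, dtype=float), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g: Array) -> None:
            self._accumulate(g)
            other._accumulate(g)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: Array) -> None:
            self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g: Array) -> None:
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g: Array) -> None:
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / other.data**2)

        return self._make(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float) -> "Tensor":
        def backward(g: Array) -> None:
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return self._make(self.data**exponent, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)

        def backward(g: Array) -> None:
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities --------------------------------------------------

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = np.where(self.data > 0, 1.0, slope)

        def backward(g: Array) -> None:
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def relu(self) -> "Tensor":
        return self.leaky_relu(slope=0.0)

    def exp(self) -> "Tensor":
        value = np.exp(self.data)

        def backward(g: Array) -> None:
            self._accumulate(g * value)

        return self._make(value, (self,), backward)

    def sqrt(self) -> "Tensor":
        value = np.sqrt(self.data)

        def backward(g: Array) -> None:
            self._accumulate(g * 0.5 / value)

        return self._make(value, (self,), backward)

    # -- reductions & reshaping ------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g: Array) -> None:
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def backward(g: Array) -> None:
            self._accumulate(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    # -- message-passing primitives --------------------------------------

    def gather(self, index: Array) -> "Tensor":
        """Select rows: out[k] = self[index[k]]."""
        index = np.asarray(index, dtype=np.int64)

        def backward(g: Array) -> None:
            grad = np.zeros_like(self.data)
            np.add.at(grad, index, g)
            self._accumulate(grad)

        return self._make(self.data[index], (self,), backward)

    def segment_sum(self, index: Array, num_segments: int) -> "Tensor":
        """Scatter-add rows: out[index[k]] += self[k]."""
        index = np.asarray(index, dtype=np.int64)
        out_shape = (num_segments,) + self.data.shape[1:]
        value = np.zeros(out_shape)
        np.add.at(value, index, self.data)

        def backward(g: Array) -> None:
            self._accumulate(g[index])

        return self._make(value, (self,), backward)

    def dropout(self, rate: float, rng: np.random.Generator | None) -> "Tensor":
        """Inverted dropout; identity when ``rng`` is None (evaluation mode)."""
        if rng is None or rate <= 0.0:
            return self
        mask = (rng.random(self.data.shape) >= rate) / (1.0 - rate)

        def backward(g: Array) -> None:
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    # -- backprop ---------------------------------------------------------

    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor") -> None:
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for parent in node._parents:
                visit(parent)
            topo.append(node)

        import sys

        limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(limit, 100000))
        try:
            visit(self)
        finally:
            sys.setrecursionlimit(limit)
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: Array) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    return Tensor(np.asarray(data, dtype=float), requires_grad=True)


def glorot(shape: tuple[int, ...], rng: np.random.Generator) -> Tensor:
    fan_in, fan_out = shape[0], shape[-1]
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return parameter(rng.uniform(-bound, bound, size=shape))
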
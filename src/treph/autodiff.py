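"""A small reverse-mode automatic-differentiation engine over numpy arrays.

Tape-based: every operation records its parents and a backward closure; a
topological sweep from the loss accumulates gradients in float64.  The op set
is exactly what the topological layer and the GNN backbones need — broadcast
arithmetic, matmul, row gather/scatter, concatenation, sigmoid/ReLU/abs/exp/
log — nothing more.  Gradients at the kinks of ``abs``/``relu`` follow the
one-sided subgradient convention (0 at the kink).
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "scatter_add_rows", "parameters_of"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None
        self.name = name

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents: tuple["Tensor", ...],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad=None) -> None:
        """Reverse sweep from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar")
            grad = np.ones_like(self.data)
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accumulate(g)
            other._accumulate(g)
        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)
        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)
        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / other.data ** 2)
        return self._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)
        return self._make(self.data @ other.data, (self, other), bwd)

    # -- reductions & shaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(ge, self.data.shape))
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        def bwd(g):
            self._accumulate(g.reshape(self.data.shape))
        return self._make(self.data.reshape(*shape), (self,), bwd)

    @property
    def T(self):
        def bwd(g):
            self._accumulate(g.T)
        return self._make(self.data.T, (self,), bwd)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accumulate(g * mask)
        return self._make(self.data * mask, (self,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        coef = np.where(self.data > 0, 1.0, slope)

        def bwd(g):
            self._accumulate(g * coef)
        return self._make(self.data * coef, (self,), bwd)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accumulate(g * s * (1.0 - s))
        return self._make(s, (self,), bwd)

    def exp(self):
        e = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * e)
        return self._make(e, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accumulate(g / self.data)
        return self._make(np.log(self.data), (self,), bwd)

    def abs(self):
        sign = np.sign(self.data)

        def bwd(g):
            self._accumulate(g * sign)
        return self._make(np.abs(self.data), (self,), bwd)

    def __pow__(self, p: float):
        def bwd(g):
            self._accumulate(g * p * self.data ** (p - 1))
        return self._make(self.data ** p, (self,), bwd)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])
    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), bwd)


def gather_rows(x: Tensor, idx) -> Tensor:
    """Row lookup ``x[idx]`` (idx is a constant int array)."""
    idx = np.asarray(idx, dtype=np.int64)

    def bwd(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, idx, g)
        x._accumulate(acc)
    return Tensor._make(x.data[idx], (x,), bwd)


def scatter_add_rows(src: Tensor, idx, n_rows: int) -> Tensor:
    """Sum rows of ``src`` into an ``(n_rows, d)`` output at positions ``idx``."""
    idx = np.asarray(idx, dtype=np.int64)
    out = np.zeros((n_rows,) + src.data.shape[1:])
    np.add.at(out, idx, src.data)

    def bwd(g):
        src._accumulate(g[idx])
    return Tensor._make(out, (src,), bwd)


def parameters_of(obj) -> list[Tensor]:
    """Collect, depth-first, every requires-grad Tensor hanging off ``obj``
    (attributes, lists/tuples/dicts of modules)."""
    found: list[Tensor] = []
    seen: set[int] = set()

    def visit(o):
        if id(o) in seen:
            return
        seen.add(id(o))
        if isinstance(o, Tensor):
            if o.requires_grad:
                found.append(o)
            return
        if isinstance(o, (list, tuple)):
            for e in o:
                visit(e)
            return
        if isinstance(o, dict):
            for e in o.values():
                visit(e)
            return
        d = getattr(o, "__dict__", None)
        if d is not None:
            for e in d.values():
                visit(e)
    visit(obj)
    return found
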
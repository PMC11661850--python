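"""Compact reverse-mode automatic differentiation over numpy arrays.

The equivariant layers need only a small closed set of primitives —
broadcast arithmetic, einsum, reductions, concatenation and a few pointwise
maps — so this module provides exactly those, with a taped ``Node`` graph
and a topological-order backward pass.  Nodes wrap ``float64`` numpy arrays;
plain arrays and scalars mix freely with nodes (they simply carry no
gradient).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Node", "as_node", "concatenate", "einsum", "stack"]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reverse numpy broadcasting: reduce ``grad`` down to ``shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Node:
    """A value in the computation graph."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=None):
        self.data = np.asarray(data, dtype=float)
        self.parents = tuple(p for p in parents if isinstance(p, Node))
        self._backward = backward
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in self.parents)
        self.requires_grad = requires_grad
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph traversal ----------------------------------------------------

    def backward(self, seed: np.ndarray | None = None) -> None:
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node.parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.data) if seed is None else np.asarray(seed, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _sum_to_shape(np.asarray(grad, dtype=float), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = as_node(other)

        def bw(g):
            self._accumulate(g)
            other._accumulate(g)

        return Node(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return Node(-self.data, (self,), lambda g: self._accumulate(-g))

    def __sub__(self, other):
        return self + (-as_node(other))

    def __rsub__(self, other):
        return as_node(other) + (-self)

    def __mul__(self, other):
        other = as_node(other)

        def bw(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        return Node(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_node(other)

        def bw(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / other.data**2)

        return Node(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_node(other) / self

    def __pow__(self, exponent: float):
        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Node(self.data**exponent, (self,), bw)

    # -- pointwise maps ------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Node(out_data, (self,), lambda g: self._accumulate(g * out_data))

    def log(self):
        return Node(np.log(self.data), (self,), lambda g: self._accumulate(g / self.data))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Node(out_data, (self,), lambda g: self._accumulate(g / (2.0 * out_data)))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Node(out_data, (self,), lambda g: self._accumulate(g * (1.0 - out_data**2)))

    # -- shape ops -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Node(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g):
            self._accumulate(g.reshape(self.data.shape))

        return Node(self.data.reshape(shape), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Node(self.data[idx], (self,), bw)


def as_node(value) -> Node:
    if isinstance(value, Node):
        return value
    return Node(value, requires_grad=False)


def einsum(subscripts: str, *operands) -> Node:
    """Differentiable einsum; operands may be Nodes or plain arrays.

    Every index of each operand must appear in the output or in another
    operand (true for all contractions used in this package).
    """
    if "..." in subscripts:
        raise ValueError("ellipsis not supported; spell out batch indices")
    inputs, output = subscripts.replace(" ", "").split("->")
    specs = inputs.split(",")
    if len(specs) != len(operands):
        raise ValueError("operand count does not match subscripts")
    nodes = [as_node(op) for op in operands]
    out_data = np.einsum(subscripts, *(n.data for n in nodes))

    def bw(g):
        for i, node in enumerate(nodes):
            if not node.requires_grad:
                continue
            other_specs = [output] + [s for j, s in enumerate(specs) if j != i]
            other_ops = [g] + [n.data for j, n in enumerate(nodes) if j != i]
            sub = ",".join(other_specs) + "->" + specs[i]
            node._accumulate(np.einsum(sub, *other_ops))

    return Node(out_data, tuple(nodes), bw)


def concatenate(nodes, axis: int = 0) -> Node:
    nodes = [as_node(n) for n in nodes]
    sizes = [n.data.shape[axis] for n in nodes]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for node, start, stop in zip(nodes, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, stop)
            node._accumulate(g[tuple(sl)])

    return Node(np.concatenate([n.data for n in nodes], axis=axis), tuple(nodes), bw)


def stack(nodes, axis: int = 0) -> Node:
    nodes = [as_node(n) for n in nodes]

    def bw(g):
        for i, node in enumerate(nodes):
            node._accumulate(np.take(g, i, axis=axis))

    return Node(np.stack([n.data for n in nodes], axis=axis), tuple(nodes), bw)
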
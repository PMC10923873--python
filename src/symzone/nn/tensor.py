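"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A ``Tensor`` wraps a float32 ``ndarray`` and records the operations applied
to it; ``Tensor.backward()`` walks the recorded graph in reverse topological
order and accumulates gradients into every node created with
``requires_grad=True``.  Only the operations needed by the detection network
and the zonal loss are implemented: broadcast arithmetic, log/pow/sigmoid/
leaky-relu, elementwise max/min with deterministic tie-breaking, clamping,
reductions, reshape/transpose/flip/concatenate, and (in :mod:`.conv`) 3-D
convolution primitives.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "maximum", "minimum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        """Elementwise power with a constant exponent."""
        exponent = float(exponent)
        out_data = self.data ** np.float32(exponent)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * exponent * a.data ** np.float32(exponent - 1.0))

        return Tensor._from_op(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, s=s):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return Tensor._from_op(s, (self,), backward)

    def leaky_relu(self, negative_slope: float = 0.01) -> "Tensor":
        scale = np.where(self.data >= 0, np.float32(1.0), np.float32(negative_slope))

        def backward(g, a=self, scale=scale):
            if a.requires_grad:
                a._accum(g * scale)

        return Tensor._from_op(self.data * scale, (self,), backward)

    def clamp(self, lo: float, hi: float) -> "Tensor":
        """Clip to [lo, hi]; gradient is zero on the clipped region."""
        inside = (self.data >= lo) & (self.data <= hi)

        def backward(g, a=self, inside=inside):
            if a.requires_grad:
                a._accum(g * inside)

        return Tensor._from_op(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape))

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(a.shape))

        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes) -> "Tensor":
        inverse = np.argsort(axes)

        def backward(g, a=self, inverse=inverse):
            if a.requires_grad:
                a._accum(g.transpose(inverse))

        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    def flip(self, axis: int) -> "Tensor":
        def backward(g, a=self, axis=axis):
            if a.requires_grad:
                a._accum(np.flip(g, axis=axis))

        return Tensor._from_op(np.flip(self.data, axis=axis), (self,), backward)

    # -- autodiff driver ------------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; network graphs exceed recursion depth
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen and parent.requires_grad:
                    stack.append((parent, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concatenate(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, tensors=tensors, offsets=offsets, axis=axis):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                index = [slice(None)] * g.ndim
                index[axis] = slice(lo, hi)
                t._accum(g[tuple(index)])

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; on ties the gradient is routed to `a` (fixed precedence)."""
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    take_a = a.data >= b.data

    def backward(g, a=a, b=b, take_a=take_a):
        if a.requires_grad:
            a._accum(_unbroadcast(g * take_a, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~take_a, b.shape))

    return Tensor._from_op(np.where(take_a, a.data, b.data), (a, b), backward)


def minimum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise min; on ties the gradient is routed to `a` (fixed precedence)."""
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    take_a = a.data <= b.data

    def backward(g, a=a, b=b, take_a=take_a):
        if a.requires_grad:
            a._accum(_unbroadcast(g * take_a, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~take_a, b.shape))

    return Tensor._from_op(np.where(take_a, a.data, b.data), (a, b), backward)
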
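"""Minimal reverse-mode automatic differentiation over numpy arrays.

The whole network (encoders, attention fusion, heads, decoders) and every
training objective are expressed as compositions of the primitives below, so a
single backward pass yields exact gradients for full-batch optimization.  All
arithmetic is float64, which keeps finite-difference gradient checks tight and
runs bit-identically for a fixed seed.

Only the primitives the model actually needs are implemented: affine maps,
elementwise nonlinearities, row softmax, reductions, and the scalar ops the
loss functions require.  Broadcasting follows numpy semantics; gradients of
broadcast operands are summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "maximum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # collapse leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._node(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._node(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._node(data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return self._node(data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return self._node(data, (self, other), backward)

    @property
    def T(self) -> "Tensor":
        return self._node(self.data.T, (self,), lambda g: (g.T,))

    # -- elementwise ----------------------------------------------------------
    def exp(self) -> "Tensor":
        data = np.exp(self.data)
        return self._node(data, (self,), lambda g: (g * data,))

    def log(self) -> "Tensor":
        return self._node(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self) -> "Tensor":
        data = np.sqrt(self.data)
        return self._node(data, (self,), lambda g: (g / (2.0 * data),))

    def elu(self, alpha: float = 1.0) -> "Tensor":
        pos = self.data > 0
        data = np.where(pos, self.data, alpha * np.expm1(self.data))

        def backward(g):
            return (g * np.where(pos, 1.0, data + alpha),)

        return self._node(data, (self,), backward)

    def softplus(self) -> "Tensor":
        # stable: log(1 + e^x) = max(x, 0) + log1p(e^{-|x|})
        data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))

        def backward(g):
            return (g / (1.0 + np.exp(-self.data)),)

        return self._node(data, (self,), backward)

    # -- reductions and structured ops ---------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._node(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def row_softmax(self) -> "Tensor":
        """Softmax along the last axis."""
        shifted = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        data = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            inner = (g * data).sum(axis=-1, keepdims=True)
            return (data * (g - inner),)

        return self._node(data, (self,), backward)

    # -- graph traversal -------------------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of this scalar into every reachable leaf."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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

        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
        # leaves whose gradient arrived exactly at the output node
        if self._backward is None and self.requires_grad:
            pass

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along `axis` with gradient routing back to each operand."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(data, tensors, backward)


def maximum(t: Tensor, floor: float) -> Tensor:
    """Elementwise max with a constant; subgradient 0 on the floored branch."""
    t = Tensor._lift(t)
    mask = t.data > floor
    data = np.where(mask, t.data, floor)
    return Tensor._node(data, (t,), lambda g: (g * mask,))
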
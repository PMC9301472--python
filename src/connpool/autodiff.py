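"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model in :mod:`connpool.model` is small (a few dozen tensor operations
per forward pass) but needs exact gradients with respect to both its
parameters and its input connectivity matrix — the latter is the saliency
map.  This module provides just the operations that model requires:
broadcasting arithmetic, (batched) matmul, axis reductions, elementwise
nonlinearities, row/column gather, reshape/transpose and concatenation.

Gradients are accumulated by topological-order backpropagation from a
scalar root.  All data is kept in float64; every backward rule is covered
by central-finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "constant",
    "concatenate",
    "sigmoid",
    "leaky_relu",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from size 1
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery ------------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from this scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar root tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        out._backward = bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = bw
        return out

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.data.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def take(self, indices, axis: int):
        """Gather the given indices along ``axis`` (backward scatters)."""
        indices = np.asarray(indices, dtype=np.intp)
        out = Tensor(np.take(self.data, indices, axis=axis), self.requires_grad, (self,))
        shape = self.data.shape

        def bw(g):
            if self.requires_grad:
                full = np.zeros(shape, dtype=np.float64)
                idx = [slice(None)] * len(shape)
                for pos, src in enumerate(indices):
                    idx[axis] = src
                    gsel = np.take(g, pos, axis=axis)
                    full[tuple(idx)] += gsel
                self._accumulate(full)

        out._backward = bw
        return out

    def take_batched(self, indices: np.ndarray):
        """Per-sample gather along axis 1: ``out[b, i] = x[b, idx[b, i]]``.

        ``indices`` has shape (B, k); trailing axes are carried along.
        Backward scatter-adds into the source positions.
        """
        indices = np.asarray(indices, dtype=np.intp)
        bgrid = np.arange(self.data.shape[0])[:, None]
        out = Tensor(self.data[bgrid, indices], self.requires_grad, (self,))
        shape = self.data.shape

        def bw(g):
            if self.requires_grad:
                full = np.zeros(shape, dtype=np.float64)
                np.add.at(full, (bgrid, indices), g)
                self._accumulate(full)

        out._backward = bw
        return out

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))
        shape = self.data.shape

        def bw(g):
            if self.requires_grad:
                if axis is None:
                    self._accumulate(np.broadcast_to(g, shape).copy())
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self._accumulate(np.broadcast_to(gg, shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            count = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int):
        """Max along one axis; gradient flows to the first maximising entry."""
        argmax = np.argmax(self.data, axis=axis)
        out = Tensor(np.max(self.data, axis=axis), self.requires_grad, (self,))
        shape = self.data.shape

        def bw(g):
            if self.requires_grad:
                full = np.zeros(shape, dtype=np.float64)
                grid = np.indices(g.shape)
                idx = list(grid)
                idx.insert(axis, argmax)
                full[tuple(idx)] = g
                self._accumulate(full)

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    """A tensor that never receives gradient."""
    return Tensor(np.asarray(x, dtype=np.float64))


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    # numerically stable logistic: exp of a nonpositive argument only
    e = np.exp(-np.abs(x.data))
    val = np.where(x.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    out = Tensor(val, x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * val * (1.0 - val))

    out._backward = bw
    return out


def leaky_relu(x: Tensor, slope: float) -> Tensor:
    x = as_tensor(x)
    mask = x.data >= 0
    out = Tensor(np.where(mask, x.data, slope * x.data), x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * np.where(mask, 1.0, slope))

    out._backward = bw
    return out
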
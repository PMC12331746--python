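"""Reverse-mode automatic differentiation on NumPy arrays.

This is the numerical engine behind the video network: a small tensor type
that records an operation graph and back-propagates gradients through it.
Only the operations the model needs are implemented (broadcasted arithmetic,
stacked matmul, 3-D convolution by shift-and-matmul, pooling/upsampling,
softmax/log-softmax, the usual pointwise nonlinearities).  Everything is
float32 end to end.

Gradient correctness for every primitive is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "concat", "stack", "default_dtype"]

_GRAD_ENABLED = [True]
_DTYPE = [np.float32]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (evaluation mode / inference)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


@contextlib.contextmanager
def default_dtype(dtype):
    """Temporarily change the engine's floating dtype (float64 for grad checks)."""
    _DTYPE.append(np.dtype(dtype))
    try:
        yield
    finally:
        _DTYPE.pop()


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=_DTYPE[-1])


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an attached backward graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "retain_grad")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED[-1]
        self.retain_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Iterable["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        req = _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents)
        out = Tensor(data)
        out.requires_grad = req
        if req:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- autodiff entry point -------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo = _toposort(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in topo:
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free interior gradients and graph edges as we go so memory
                # is reused within a single backward pass
                if node is not self:
                    node._backward = None
                    node._parents = ()
                    if not node.retain_grad:
                        node.grad = None

    def zero_graph(self) -> None:
        self._parents = ()
        self._backward = None

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * data / other.data, other.shape))

        return Tensor._make(data, (self, other), bwd)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        data = self.data ** p

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(data, (self,), bwd)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._make(data, (self, other), bwd)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        data = self.data.reshape(shape)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(data, (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        data = self.data.transpose(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(data, (self,), bwd)

    def __getitem__(self, idx):
        data = self.data[idx]
        advanced = any(isinstance(i, (list, np.ndarray)) for i in
                       (idx if isinstance(idx, tuple) else (idx,)))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if advanced:
                    np.add.at(full, idx, g)
                else:
                    full[idx] += g
                self._accum(full)

        return Tensor._make(data, (self,), bwd)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if self.requires_grad:
                if axis is None:
                    self._accum(np.broadcast_to(g, self.shape).astype(self.data.dtype))
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self._accum(np.broadcast_to(gg, self.shape).astype(self.data.dtype))

        return Tensor._make(data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else _axis_size(self.shape, axis)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        data = self.data.max(axis=axis, keepdims=keepdims)

        def bwd(g):
            if self.requires_grad:
                dk = data if keepdims or axis is None else np.expand_dims(data, axis)
                gk = g if keepdims or axis is None else np.expand_dims(g, axis)
                mask = (self.data == dk).astype(self.data.dtype)
                mask /= np.maximum(mask.sum(axis=axis, keepdims=True), 1.0) \
                    if axis is not None else np.maximum(mask.sum(), 1.0)
                self._accum(mask * gk)

        return Tensor._make(data, (self,), bwd)

    # -- pointwise nonlinearities ---------------------------------------------

    def relu(self):
        data = np.maximum(self.data, 0.0)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        return Tensor._make(data, (self,), bwd)

    def gelu(self):
        # tanh approximation of the Gaussian error linear unit
        x = self.data
        c = self.data.dtype.type(np.sqrt(2.0 / np.pi))
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        data = 0.5 * x * (1.0 + t)

        def bwd(g):
            if self.requires_grad:
                dt = (1.0 - t ** 2) * c * (1.0 + 3 * 0.044715 * x ** 2)
                self._accum(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        return Tensor._make(data, (self,), bwd)

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * data * (1.0 - data))

        return Tensor._make(data, (self,), bwd)

    def tanh(self):
        data = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - data ** 2))

        return Tensor._make(data, (self,), bwd)

    def exp(self):
        data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * data)

        return Tensor._make(data, (self,), bwd)

    def log(self):
        data = np.log(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(data, (self,), bwd)

    def sqrt(self):
        data = np.sqrt(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * 0.5 / data)

        return Tensor._make(data, (self,), bwd)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        data = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if self.requires_grad:
                dot = (g * data).sum(axis=axis, keepdims=True)
                self._accum(data * (g - dot))

        return Tensor._make(data, (self,), bwd)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        data = z - lse
        sm = np.exp(data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g - sm * g.sum(axis=axis, keepdims=True))

        return Tensor._make(data, (self,), bwd)


def _axis_size(shape: Sequence[int], axis) -> int:
    if isinstance(axis, int):
        axis = (axis,)
    n = 1
    for a in axis:
        n *= shape[a]
    return n


def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    order.reverse()
    return order


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(data, tensors, bwd)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(data, tensors, bwd)
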
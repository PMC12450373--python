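"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the reference transformer encoder and the
three fine-tuning losses need: broadcasting arithmetic, (stacked) matrix
multiplication, elementwise exp/log/tanh/relu/abs/power, axis reductions,
reshape/transpose, and advanced row indexing (embedding gather).  All data
is float64.  Gradients are accumulated by topological sort from the output
scalar; correctness is checked against central finite differences in the
test suite.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "log_softmax", "softmax", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = any(p.requires_grad for p in parents) or any(
                p._parents for p in parents
            )
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(grad, self=self, other=other):
            return (_unbroadcast(grad, self.shape), _unbroadcast(grad, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(grad, self=self):
            return (-grad,)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(grad, self=self, other=other):
            return (
                _unbroadcast(grad * other.data, self.shape),
                _unbroadcast(grad * self.data, other.shape),
            )

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(grad, self=self, other=other):
            return (
                _unbroadcast(grad / other.data, self.shape),
                _unbroadcast(-grad * self.data / other.data**2, other.shape),
            )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(grad, self=self, exponent=exponent):
            return (grad * exponent * self.data ** (exponent - 1),)

        return Tensor._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(grad, self=self, other=other):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                return (grad * b, grad * a)
            if a.ndim == 1:  # (k,) @ (..., k, n)
                ga = (np.expand_dims(grad, -2) @ np.swapaxes(b, -1, -2)).reshape(
                    grad.shape[:-1] + a.shape
                )
                gb = np.expand_dims(a, -1) * np.expand_dims(grad, -2)
                return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))
            if b.ndim == 1:  # (..., m, k) @ (k,)
                ga = np.expand_dims(grad, -1) * b
                gb = np.swapaxes(a, -1, -2) @ np.expand_dims(grad, -1)
                return (
                    _unbroadcast(ga, a.shape),
                    _unbroadcast(gb.reshape(gb.shape[:-1]), b.shape),
                )
            ga = grad @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ grad
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- elementwise ----------------------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(grad, out_data=out_data):
            return (grad * out_data,)

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(grad, self=self):
            return (grad / self.data,)

        return Tensor._make(np.log(self.data), (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(grad, out_data=out_data):
            return (grad * (1.0 - out_data**2),)

        return Tensor._make(out_data, (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(grad, mask=mask):
            return (grad * mask,)

        return Tensor._make(self.data * mask, (self,), backward)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)

        def backward(grad, sign=sign):
            return (grad * sign,)

        return Tensor._make(np.abs(self.data), (self,), backward)

    def sqrt(self) -> "Tensor":
        return self**0.5

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(grad, self=self, axis=axis, keepdims=keepdims):
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(grad, self=self):
            return (grad.reshape(self.shape),)

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def backward(grad, a=a, b=b):
            return (np.swapaxes(grad, a, b),)

        return Tensor._make(np.swapaxes(self.data, a, b), (self,), backward)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def backward(grad, inv=inv):
            return (np.transpose(grad, inv),)

        return Tensor._make(np.transpose(self.data, axes), (self,), backward)

    @property
    def T(self) -> "Tensor":
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx) -> "Tensor":
        def backward(grad, self=self, idx=idx):
            g = np.zeros_like(self.data)
            np.add.at(g, idx, grad)
            return (g,)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo = _postorder(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            grad = grads.pop(id(node), None)
            if grad is None:
                continue
            if node.requires_grad:
                node.grad = grad if node.grad is None else node.grad + grad
            if node._backward is None:
                continue
            for parent, g in zip(node._parents, node._backward(grad)):
                if g is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + g
                else:
                    grads[key] = g


def _postorder(root: Tensor) -> list[Tensor]:
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
        for parent in node._parents:
            if id(parent) not in seen:
                stack.append((parent, False))
    return order


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    # Subtracting the (detached) max is gradient-exact: softmax is shift
    # invariant, so the offset contributes zero gradient.
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def stack(tensors: Iterable[Tensor]) -> Tensor:
    """Stack 1-D tensors into a 2-D tensor along a new leading axis."""
    tensors = list(tensors)
    data = np.stack([t.data for t in tensors])

    def backward(grad, tensors=tensors):
        return tuple(grad[i] for i in range(len(tensors)))

    return Tensor._make(data, tuple(tensors), backward)
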
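"""Tiny reverse-mode automatic differentiation over NumPy arrays.

Only the operations needed by the recurrent encoder and its losses are
implemented.  Broadcasting follows NumPy semantics; gradients of broadcast
operands are summed back to the operand's shape.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["Tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make `ndarray op Tensor` defer to Tensor's reflected operators
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = np.array(g)  # copy: g may alias upstream buffers
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward():
            self._accum(out.grad)
            other._accum(out.grad)

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward():
            self._accum(-out.grad)

        out = self._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward():
            self._accum(out.grad * other.data)
            other._accum(out.grad * self.data)

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward():
            self._accum(out.grad / other.data)
            other._accum(-out.grad * self.data / other.data**2)

        out = self._make(out_data, (self, other), backward)
        return out

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward():
            self._accum(out.grad * p * self.data ** (p - 1))

        out = self._make(out_data, (self,), backward)
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward():
            self._accum(out.grad @ other.data.T)
            other._accum(self.data.T @ out.grad)

        out = self._make(out_data, (self, other), backward)
        return out

    # -- elementwise nonlinearities ----------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward():
            self._accum(out.grad * out_data)

        out = self._make(out_data, (self,), backward)
        return out

    def log(self):
        def backward():
            self._accum(out.grad / self.data)

        out = self._make(np.log(self.data), (self,), backward)
        return out

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward():
            self._accum(out.grad * (1.0 - out_data**2))

        out = self._make(out_data, (self,), backward)
        return out

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward():
            self._accum(out.grad * out_data * (1.0 - out_data))

        out = self._make(out_data, (self,), backward)
        return out

    def relu(self):
        mask = self.data > 0

        def backward():
            self._accum(out.grad * mask)

        out = self._make(self.data * mask, (self,), backward)
        return out

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward():
            self._accum(out.grad * 0.5 / out_data)

        out = self._make(out_data, (self,), backward)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp; gradient is zero outside [lo, hi]."""
        mask = (self.data >= lo) & (self.data <= hi)

        def backward():
            self._accum(out.grad * mask)

        out = self._make(np.clip(self.data, lo, hi), (self,), backward)
        return out

    def maximum(self, other: float):
        """Elementwise max with a constant (hinge); ties route gradient to self."""
        mask = self.data >= other

        def backward():
            self._accum(out.grad * mask)

        out = self._make(np.maximum(self.data, other), (self,), backward)
        return out

    # -- shape ops ----------------------------------------------------------

    def __getitem__(self, idx):
        out_data = self.data[idx]
        advanced = any(isinstance(i, (np.ndarray, list)) for i in
                       (idx if isinstance(idx, tuple) else (idx,)))

        def backward():
            g = np.zeros_like(self.data)
            if advanced:  # duplicate indices must accumulate
                np.add.at(g, idx, out.grad)
            else:
                g[idx] += out.grad
            self._accum(g)

        out = self._make(out_data, (self,), backward)
        return out

    def reshape(self, *shape):
        orig = self.data.shape

        def backward():
            self._accum(out.grad.reshape(orig))

        out = self._make(self.data.reshape(*shape), (self,), backward)
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    @staticmethod
    def concatenate(tensors: list["Tensor"], axis: int = 0) -> "Tensor":
        tensors = [Tensor._wrap(t) for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward():
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * out_data.ndim
                sl[axis] = slice(a, b)
                t._accum(out.grad[tuple(sl)])

        out = tensors[0]._make(out_data, tuple(tensors), backward)
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"
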
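"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine supports exactly the operations the embedding network and its
losses need: broadcast arithmetic, matrix products, 2-D convolution via
im2col, pooling, ReLU, log-softmax, row gathering, reductions and square
root. Gradients accumulate into ``Tensor.grad`` after :meth:`Tensor.backward`
on a scalar. Everything is float64 by default for reproducibility; there is
no device abstraction and no graph retention between backward calls.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away leading dims
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bwd():
            if self.requires_grad:
                self._accumulate(-out.grad)

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(
                    -out.grad * self.data / (other.data ** 2), other.data.shape))

        out._backward = bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd():
            if self.requires_grad:
                self._accumulate(out.grad @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ out.grad)

        out._backward = bwd
        return out

    __matmul__ = matmul

    # ------------------------------------------------------------ elementwise
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def bwd():
            if self.requires_grad:
                self._accumulate(out.grad * mask)

        out._backward = bwd
        return out

    def sqrt(self) -> "Tensor":
        val = np.sqrt(self.data)
        out = Tensor(val, self.requires_grad, (self,))

        def bwd():
            if self.requires_grad:
                self._accumulate(out.grad * 0.5 / np.maximum(val, 1e-300))

        out._backward = bwd
        return out

    # -------------------------------------------------------------- shape ops
    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bwd():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.data.shape))

        out._backward = bwd
        return out

    def take_rows(self, idx) -> "Tensor":
        """Gather rows (axis 0); duplicate indices accumulate gradient."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accumulate(g)

        out._backward = bwd
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ---------------------------------------------------------------- softmax
    def log_softmax(self) -> "Tensor":
        """Row-wise log-softmax for an (n, c) tensor."""
        x = self.data
        m = x.max(axis=1, keepdims=True)
        z = x - m
        lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
        val = z - lse
        out = Tensor(val, self.requires_grad, (self,))

        def bwd():
            if self.requires_grad:
                sm = np.exp(val)
                self._accumulate(out.grad - sm * out.grad.sum(axis=1, keepdims=True))

        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
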
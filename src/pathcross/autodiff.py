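"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This module provides the :class:`Tensor` primitive used by the neural-network
layers in :mod:`pathcross.nn`.  It is deliberately small: only the operations
required by the pathway transformer are implemented, each with an explicit
vector-Jacobian product.  All operations support NumPy broadcasting; gradients
of broadcast operands are summed back to the operand's shape.

Shapes follow the batch-last-two convention of ``numpy.matmul``: ``matmul``
accepts stacked matrices with arbitrary leading batch dimensions on either
side, which is what lets the attention code evaluate all heads in one call.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, ndtr  # logistic and normal CDF

__all__ = ["Tensor", "concatenate", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (evaluation mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the dimensions that were broadcast to reach it."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=False)


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._vjp = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _make(data, parents, vjp):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._vjp = vjp
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            grad = np.ones_like(self.data)
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._vjp is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if not parent.requires_grad or pg is None:
                    continue
                pg = _unbroadcast(pg, parent.data.shape)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
        # leaves already handled in the loop above (vjp is None)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor._make(self.data + other.data, (self, other),
                            lambda g: (g, g))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = _as_tensor(other)
        return Tensor._make(self.data - other.data, (self, other),
                            lambda g: (g, -g))

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor._make(self.data * other.data, (self, other),
                            lambda g: (g * other.data, g * self.data))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return Tensor._make(
            self.data / other.data, (self, other),
            lambda g: (g / other.data, -g * self.data / other.data ** 2))

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        return Tensor._make(self.data ** e, (self,),
                            lambda g: (g * e * self.data ** (e - 1.0),))

    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self.data, other.data

        def vjp(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return ga, gb

        return Tensor._make(a @ b, (self, other), vjp)

    def __getitem__(self, idx):
        def vjp(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(self.data[idx], (self,), vjp)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.data.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), vjp)

    def max(self, axis: int = -1, keepdims: bool = False):
        out = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out)
        mask = mask / mask.sum(axis=axis, keepdims=True)  # split ties evenly

        def vjp(g):
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (g2 * mask,)

        return Tensor._make(out if keepdims else np.squeeze(out, axis=axis),
                            (self,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis] if isinstance(axis, int) else int(
                np.prod([self.data.shape[a] for a in axis]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(old),))

    def swapaxes(self, a: int, b: int):
        return Tensor._make(np.swapaxes(self.data, a, b), (self,),
                            lambda g: (np.swapaxes(g, a, b),))

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,),
                            lambda g: (g / self.data,))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, (self,), lambda g: (g * 0.5 / out,))

    def sigmoid(self):
        out = expit(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out * (1.0 - out),))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._make(out, (self,), lambda g: (g * (1.0 - out ** 2),))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def gelu(self):
        """Exact GELU, x * Phi(x), with analytic derivative."""
        x = self.data
        phi = ndtr(x)
        pdf = np.exp(-0.5 * x ** 2) / np.sqrt(2.0 * np.pi)
        return Tensor._make(x * phi, (self,), lambda g: (g * (phi + x * pdf),))

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)
        return Tensor._make(np.clip(self.data, lo, hi), (self,),
                            lambda g: (g * mask,))

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along ``axis``."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=axis, keepdims=True)

        def vjp(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            return ((g - dot) * out,)

        return Tensor._make(out, (self,), vjp)

    def logsumexp(self, axis: int = -1, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        s = e.sum(axis=axis, keepdims=True)
        out = m + np.log(s)
        soft = e / s

        def vjp(g):
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (g2 * soft,)

        return Tensor._make(out if keepdims else np.squeeze(out, axis=axis),
                            (self,), vjp)


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` (differentiable)."""
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, vjp)
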
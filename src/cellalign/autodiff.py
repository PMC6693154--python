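"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the encoder/decoder networks and the walker
objective: broadcast-aware arithmetic, matmul, exp/log/relu/power, axis
reductions and a floor clamp.  Gradients are exact (verified against central
finite differences in the test suite), float64 throughout.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = _parents
        self._backward = None

    # -- helpers --------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req, _parents=parents if req else ())
        if req:
            out._backward = backward
        return out

    def _accum(self, grad):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = self._make(self.data + other.data, (self, other), None)

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = self._make(self.data / other.data, (self, other), None)

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __matmul__(self, other):
        other = self._wrap(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def backward(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = backward
        return out

    @property
    def T(self) -> "Tensor":
        out = self._make(self.data.T, (self,), None)
        out._backward = lambda g: self._accum(g.T)
        return out

    # -- elementwise ----------------------------------------------------
    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = self._make(e, (self,), None)
        out._backward = lambda g: self._accum(g * e)
        return out

    def log(self) -> "Tensor":
        out = self._make(np.log(self.data), (self,), None)
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)
        out._backward = lambda g: self._accum(g * mask)
        return out

    def pow_const(self, p: float) -> "Tensor":
        out = self._make(self.data**p, (self,), None)
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def sqrt(self) -> "Tensor":
        return self.pow_const(0.5)

    def clip_min(self, floor: float) -> "Tensor":
        """max(x, floor); gradient passes only where x > floor."""
        mask = self.data > floor
        out = self._make(np.maximum(self.data, floor), (self,), None)
        out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            count = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- backward pass --------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.ones_like(self.data)}
        self.grad = grads[id(self)] if self.requires_grad else None

        # propagate by walking in reverse topological order; each node's
        # _backward closure accumulates into its parents' .grad
        for t in topo:
            if t.grad is None and t is not self:
                t.grad = None
        if not self.requires_grad:
            return
        # seed and run
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def softmax_rows(z: Tensor) -> Tensor:
    """Row-wise softmax; the max-shift is treated as a constant (its gradient
    contribution cancels exactly)."""
    shift = Tensor(z.data.max(axis=1, keepdims=True))
    e = (z - shift).exp()
    return e / e.sum(axis=1, keepdims=True)


def log_softmax_rows(z: Tensor) -> Tensor:
    shift = Tensor(z.data.max(axis=1, keepdims=True))
    zs = z - shift
    return zs - zs.exp().sum(axis=1, keepdims=True).log()
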
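"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery to express multilayer perceptrons, reparameterised
Gaussian sampling and the closed-form KL terms of the dual-VAE objective:
matmul, broadcast add, elementwise arithmetic, relu, exp, concatenation and
reductions.  Gradients are accumulated by topological-order backpropagation
and are validated against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1
                 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(),
                 backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, parents=parents,
                      backward=backward if req else None)

    # -- operations ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def back(out_grad, a=self, b=other):
            return (_unbroadcast(out_grad, a.shape),
                    _unbroadcast(out_grad, b.shape))
        return self._make(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __sub__(self, other):
        other = self._lift(other)

        def back(out_grad, a=self, b=other):
            return (_unbroadcast(out_grad, a.shape),
                    _unbroadcast(-out_grad, b.shape))
        return self._make(self.data - other.data, (self, other), back)

    def __rsub__(self, other):
        return self._lift(other) - self

    def __mul__(self, other):
        other = self._lift(other)

        def back(out_grad, a=self, b=other):
            return (_unbroadcast(out_grad * b.data, a.shape),
                    _unbroadcast(out_grad * a.data, b.shape))
        return self._make(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __matmul__(self, other):
        other = self._lift(other)

        def back(out_grad, a=self, b=other):
            return out_grad @ b.data.T, a.data.T @ out_grad
        return self._make(self.data @ other.data, (self, other), back)

    def relu(self):
        mask = self.data > 0

        def back(out_grad, m=mask):
            return (out_grad * m,)
        return self._make(self.data * mask, (self,), back)

    def exp(self):
        out = np.exp(self.data)

        def back(out_grad, o=out):
            return (out_grad * o,)
        return self._make(out, (self,), back)

    def square(self):
        def back(out_grad, a=self):
            return (out_grad * 2.0 * a.data,)
        return self._make(self.data ** 2, (self,), back)

    def sum(self):
        def back(out_grad, a=self):
            return (np.broadcast_to(out_grad, a.shape).copy(),)
        return self._make(self.data.sum(), (self,), back)

    def mean(self):
        n = self.data.size

        def back(out_grad, a=self, n=n):
            return (np.broadcast_to(out_grad / n, a.shape).copy(),)
        return self._make(self.data.mean(), (self,), back)

    @staticmethod
    def concat(tensors, axis: int = 1) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def back(out_grad, axis=axis, splits=splits):
            return tuple(np.split(out_grad, splits, axis=axis))
        out = np.concatenate([t.data for t in tensors], axis=axis)
        req = any(t.requires_grad for t in tensors)
        return Tensor(out, requires_grad=req, parents=tuple(tensors),
                      backward=back if req else None)

    # -- backpropagation --------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs must not hit the recursion limit
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
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)


class Adam:
    """Adam optimiser over a list of parameter :class:`Tensor` objects."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
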
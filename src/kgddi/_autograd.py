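"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A tape-based scalar-loss autodiff engine: each :class:`Tensor` wraps an
``ndarray`` and remembers how it was produced; ``backward()`` walks the tape
in reverse topological order accumulating gradients. Supports exactly the
operations the embedding and factorization-machine trainers need (broadcasted
arithmetic, matmul, row gather with scatter-add gradient, softmax, the usual
nonlinearities and reductions). Gradient correctness is verified against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "gather", "relu", "sigmoid", "softmax", "tanh"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bwd(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._from_op(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._from_op(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bwd(g, out):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._from_op(self.data / other.data, (self, other), bwd)

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data

        def bwd(g, out):
            if a.ndim == 1 and b.ndim == 2:
                return (g @ b.T, np.outer(a, g))
            if a.ndim == 2 and b.ndim == 1:
                return (np.outer(g, b), a.T @ g)
            ga = g @ np.swapaxes(b, -1, -2)
            if b.ndim == 2 and a.ndim > 2:
                # batched activations against a shared weight: contract all
                # leading axes at once instead of materializing per-batch grads
                gb = np.tensordot(a, g, axes=(tuple(range(a.ndim - 1)), tuple(range(g.ndim - 1))))
            else:
                gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
            return (_unbroadcast(ga, a.shape), gb)

        return Tensor._from_op(a @ b, (self, other), bwd)

    def __pow__(self, p: float):
        def bwd(g, out):
            return (g * p * self.data ** (p - 1),)

        return Tensor._from_op(self.data**p, (self,), bwd)

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g, out):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def bwd(g, out):
            return (g.reshape(self.shape),)

        return Tensor._from_op(self.data.reshape(*shape), (self,), bwd)

    def log(self):
        def bwd(g, out):
            return (g / self.data,)

        return Tensor._from_op(np.log(self.data), (self,), bwd)

    def exp(self):
        def bwd(g, out):
            return (g * out.data,)

        return Tensor._from_op(np.exp(self.data), (self,), bwd)

    # -- backward pass --------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs exceed the recursion limit
            node, done = stack.pop()
            if done:
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
            grads = node._backward(node.grad, node)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self):
        self.grad = None


# -- free functions -----------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor._from_op(x.data * mask, (x,), lambda g, out: (g * mask,))


def tanh(x: Tensor) -> Tensor:
    def bwd(g, out):
        return (g * (1.0 - out.data**2),)

    return Tensor._from_op(np.tanh(x.data), (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    # tanh identity is overflow-free in both tails
    y = 0.5 * (1.0 + np.tanh(0.5 * x.data))

    def bwd(g, out):
        return (g * out.data * (1.0 - out.data),)

    return Tensor._from_op(y, (x,), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g, out):
        dot = (g * out.data).sum(axis=axis, keepdims=True)
        return (out.data * (g - dot),)

    return Tensor._from_op(y, (x,), bwd)


def gather(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup ``table[idx]``; gradient scatter-adds back into the table."""
    idx = np.asarray(idx)

    flat = idx.reshape(-1)
    order = np.argsort(flat, kind="stable")
    sorted_idx = flat[order]
    starts = np.flatnonzero(np.r_[True, sorted_idx[1:] != sorted_idx[:-1]])
    uniq = sorted_idx[starts]

    def bwd(g, out):
        # segment-sum per unique row (sort + reduceat beats np.add.at here)
        gt = np.zeros_like(table.data)
        rows = g.reshape(-1, table.data.shape[-1])[order]
        gt[uniq] = np.add.reduceat(rows, starts, axis=0)
        return (gt,)

    return Tensor._from_op(table.data[idx], (table,), bwd)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g, out):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )


class Adam:
    """Adaptive-moment-estimation optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 0.005,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
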
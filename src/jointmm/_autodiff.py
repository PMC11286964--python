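"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the transformer encoder, its prediction
heads and the Cox partial-likelihood loss need: broadcasting arithmetic,
batched matmul, softmax, relu, exp/log/pow, reductions, reshaping,
concatenation and slicing.  Gradients flow to parameters only; inputs are
wrapped as constants.  Correctness is pinned to finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _from_op(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))
        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)
        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))
        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / b.data**2, b.shape))
        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))
        return Tensor._from_op(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))
        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        def backward(g, a=self, d=out_data):
            if a.requires_grad:
                a._accum(g * d)
        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)
        return Tensor._from_op(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0
        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)
        return Tensor._from_op(self.data * mask, (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)
        def backward(g, a=self, y=y, axis=axis):
            if a.requires_grad:
                a._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))
        return Tensor._from_op(y, (self,), backward)

    # -- reductions & shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())
        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(a.shape))
        return Tensor._from_op(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, a1: int, a2: int):
        def backward(g, a=self, a1=a1, a2=a2):
            if a.requires_grad:
                a._accum(np.swapaxes(g, a1, a2))
        return Tensor._from_op(np.swapaxes(self.data, a1, a2), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self, idx=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)
        return Tensor._from_op(self.data[idx], (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def _accum(self, g: np.ndarray):
        self.grad = g if self.grad is None else self.grad + g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def backward(g, tensors=tensors, offsets=offsets, axis=axis):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])
    return Tensor._from_op(data, tuple(tensors), backward)


class Adam:
    """Adam optimizer over a dict of named parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
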
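"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: each :class:`Tensor` wraps a float64
ndarray and remembers how it was produced, so a single call to
:meth:`Tensor.backward` accumulates gradients for every upstream tensor with
``requires_grad=True``.  Only the operations the model needs are implemented
(broadcasted arithmetic, batched matmul, matrix inverse, reductions, the
activation functions, concatenation and basic indexing).  All computation is
double precision, which keeps training runs bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as scipy_special_expit

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "elu",
    "leaky_relu",
    "softplus",
    "matmul",
    "inv",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were introduced or stretched by broadcasting."""
    if grad.shape == shape:
        return grad
    # leading axes not present in the target shape
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
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
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:  # free intermediate grads; leaves keep theirs
                node.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / other.data**2)

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bwd
        return out

    # ------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inverse = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inverse))
        return out

    @property
    def T(self):
        return self.transpose()

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), _parents=(self,))
        out._backward = lambda g: self._accumulate(np.swapaxes(g, a, b))
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * np.sign(self.data))
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with broadcasting over leading axes."""
    out = Tensor(a.data @ b.data, _parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            if b.data.ndim == 1:
                ga = np.multiply.outer(g, b.data) if g.ndim else g * b.data
            else:
                ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(ga)
        if b.requires_grad:
            if a.data.ndim == 1:
                gb = np.multiply.outer(a.data, g) if g.ndim else a.data * g
            else:
                gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(gb)

    out._backward = bwd
    return out


def inv(a: Tensor) -> Tensor:
    """Matrix inverse; gradient is -X^{-T} g X^{-T}."""
    inv_data = np.linalg.inv(a.data)
    out = Tensor(inv_data, _parents=(a,))

    def bwd(g):
        it = np.swapaxes(inv_data, -1, -2)
        a._accumulate(-it @ g @ it)

    out._backward = bwd
    return out


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = x.data > 0
    out_data = np.where(pos, x.data, alpha * np.expm1(x.data))
    out = Tensor(out_data, _parents=(x,))
    out._backward = lambda g: x._accumulate(g * np.where(pos, 1.0, out_data + alpha))
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    pos = x.data > 0
    out = Tensor(np.where(pos, x.data, slope * x.data), _parents=(x,))
    out._backward = lambda g: x._accumulate(g * np.where(pos, 1.0, slope))
    return out


def softplus(x: Tensor) -> Tensor:
    # log(1 + e^x) computed stably for large |x|
    out_data = np.logaddexp(0.0, x.data)
    out = Tensor(out_data, _parents=(x,))
    sig = scipy_special_expit(x.data)
    out._backward = lambda g: x._accumulate(g * sig)
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = bwd
    return out
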
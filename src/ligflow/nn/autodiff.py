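"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tensor engine: every :class:`Tensor` wraps a float64
``numpy.ndarray`` and records the closure needed to push gradients back to its
parents.  ``backward()`` runs a topological sort over the recorded graph.
Only the operations the equivariant backbone and its heads actually use are
implemented; all of them support numpy broadcasting, with gradients summed
back to the original shapes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "stack",
    "cross",
    "where",
    "maximum",
    "softmax",
    "log_softmax",
]


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (sampling / inference)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph wrapping a float64 array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        if _GRAD_ENABLED:
            self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        else:
            self.requires_grad = bool(requires_grad)
        self._parents = tuple(p for p in parents if p.requires_grad) if _GRAD_ENABLED else ()
        self._bwd = None
        if backward is not None:
            self._backward = backward

    @property
    def _backward(self):
        return self._bwd

    @_backward.setter
    def _backward(self, fn):
        # dropping the closure when the node is detached keeps inference
        # passes from retaining the whole graph through closure references
        self._bwd = fn if (self.requires_grad and self._parents) else None

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS (graphs can be a few thousand nodes deep)
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            pending = [p for p in node._parents if id(p) not in seen]
            if pending:
                stack_.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
                stack_.pop()
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                node.grad = None  # free intermediate grads; leaves keep theirs

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** (-1.0)

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def bwd(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bwd
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accumulate(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / np.maximum(val, 1e-300))
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - val ** 2))
        return out

    def sigmoid(self):
        z = np.clip(self.data, -60.0, 60.0)
        val = 1.0 / (1.0 + np.exp(-z))
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accumulate(g * val * (1.0 - val))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0.0))
        return out

    def silu(self):
        z = np.clip(self.data, -60.0, 60.0)
        sig = 1.0 / (1.0 + np.exp(-z))
        out = Tensor(self.data * sig, parents=(self,))
        out._backward = lambda g: self._accumulate(g * (sig * (1.0 + self.data * (1.0 - sig))))
        return out

    # -- reductions / shaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), parents=(self,))
        out._backward = lambda g: self._accumulate(np.swapaxes(g, a, b))
        return out

    def moveaxis(self, src, dst):
        out = Tensor(np.moveaxis(self.data, src, dst), parents=(self,))
        out._backward = lambda g: self._accumulate(np.moveaxis(g, dst, src))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    out._backward = bwd
    return out


def cross(a: Tensor, b: Tensor, axis: int = -1) -> Tensor:
    """Vector cross product along ``axis`` (length-3 axis), with broadcasting."""
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(np.cross(a.data, b.data, axisa=axis, axisb=axis, axisc=axis), parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            ga = np.cross(b.data, g, axisa=axis, axisb=axis, axisc=axis)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.cross(g, a.data, axisa=axis, axisb=axis, axisc=axis)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    out._backward = bwd
    return out


def where(cond: np.ndarray, x, y) -> Tensor:
    """Select elementwise; ``cond`` is a plain boolean array (not differentiated)."""
    cond = np.asarray(cond)
    x, y = as_tensor(x), as_tensor(y)
    out = Tensor(np.where(cond, x.data, y.data), parents=(x, y))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(_unbroadcast(np.where(cond, g, 0.0), x.data.shape))
        if y.requires_grad:
            y._accumulate(_unbroadcast(np.where(cond, 0.0, g), y.data.shape))

    out._backward = bwd
    return out


def maximum(x, y) -> Tensor:
    x, y = as_tensor(x), as_tensor(y)
    return where(x.data >= y.data, x, y)


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable softmax; ``mask`` marks valid entries (invalid get 0)."""
    z = x.data
    if mask is not None:
        z = np.where(mask, z, -np.inf)
    shift = np.max(z, axis=axis, keepdims=True)
    shift = np.where(np.isfinite(shift), shift, 0.0)  # all-masked rows
    e = (x - shift).exp()
    if mask is not None:
        e = e * mask.astype(np.float64)
    denom = e.sum(axis=axis, keepdims=True)
    denom = where(denom.data > 0.0, denom, Tensor(np.ones_like(denom.data)))
    return e / denom


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = np.max(x.data, axis=axis, keepdims=True)
    shifted = x - shift
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()
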
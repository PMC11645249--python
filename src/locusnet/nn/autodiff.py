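"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the closure needed to
push gradients to its parents; ``backward()`` runs an iterative topological
sweep.  Only the operations the gene-prediction network needs are
implemented; heavy recurrent pieces (the biLSTM and the HMM posterior
layer) are single fused ops with hand-written backward passes, so the tape
stays short.  All arithmetic is float64: gradient checks against central
finite differences are part of the test suite and need the headroom.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "grad_enabled",
    "constant",
    "parameter",
    "set_default_dtype",
    "default_dtype",
]

_GRAD_STACK = [True]

#: float64 by default (the gradient checks need the headroom); training
#: harnesses may switch to float32 for speed.
_DEFAULT_DTYPE = [np.float64]


def set_default_dtype(dtype) -> None:
    _DEFAULT_DTYPE[0] = np.dtype(dtype).type


def default_dtype():
    return _DEFAULT_DTYPE[0]


@contextmanager
def no_grad():
    _GRAD_STACK.append(False)
    try:
        yield
    finally:
        _GRAD_STACK.pop()


def grad_enabled() -> bool:
    return _GRAD_STACK[-1]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Tuple["Tensor", ...] = (),
        backward: Optional[Callable[[np.ndarray], Sequence[Optional[np.ndarray]]]] = None,
    ):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE[0])
        self.grad: Optional[np.ndarray] = None
        track = grad_enabled() and (requires_grad or any(p.requires_grad for p in parents))
        self.requires_grad = track
        self._parents = parents if track else ()
        self._backward = backward if track else None

    # -- introspection ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ---------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()
        stack: List[Tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = grad.astype(self.data.dtype, copy=True)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                g = _unbroadcast(g, parent.data.shape)
                if parent.grad is None:
                    parent.grad = g.copy()
                else:
                    parent.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator overloads ----------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # -- conveniences ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    return Tensor(x)


def parameter(x) -> Tensor:
    return Tensor(x, requires_grad=True)


def _unbroadcast(g: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- primitive ops ---------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(a.data + b.data, parents=(a, b), backward=lambda g: (g, g))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data * b.data,
        parents=(a, b),
        backward=lambda g: (g * b.data, g * a.data),
    )


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out = a.data**exponent
    return Tensor(
        out,
        parents=(a,),
        backward=lambda g: (g * exponent * a.data ** (exponent - 1.0),),
    )


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return ga, gb

    return Tensor(np.matmul(a.data, b.data), parents=(a, b), backward=backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)
    return Tensor(out, parents=(a,), backward=lambda g: (g * out,))


def log(a) -> Tensor:
    a = as_tensor(a)
    return Tensor(np.log(a.data), parents=(a,), backward=lambda g: (g / a.data,))


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out = np.tanh(a.data)
    return Tensor(out, parents=(a,), backward=lambda g: (g * (1.0 - out * out),))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-a.data))
    return Tensor(out, parents=(a,), backward=lambda g: (g * out * (1.0 - out),))


def relu(a) -> Tensor:
    a = as_tensor(a)
    keep = a.data > 0
    return Tensor(np.where(keep, a.data, 0.0), parents=(a,), backward=lambda g: (g * keep,))


def clip_min(a, floor: float) -> Tensor:
    """Clip from below; gradient passes through only where unclipped."""
    a = as_tensor(a)
    keep = a.data >= floor
    return Tensor(
        np.maximum(a.data, floor), parents=(a,), backward=lambda g: (g * keep,)
    )


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        g2 = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(g2, a.data.shape).copy(),)

    return Tensor(out, parents=(a,), backward=backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return Tensor(
        a.data.reshape(shape), parents=(a,), backward=lambda g: (g.reshape(a.data.shape),)
    )


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        out = np.zeros_like(a.data)
        np.add.at(out, idx, g)
        return (out,)

    return Tensor(a.data[idx], parents=(a,), backward=backward)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        return tuple(np.split(g, np.cumsum(sizes)[:-1], axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=backward,
    )


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max subtraction is treated as constant)."""
    a = as_tensor(a)
    shifted = add(a, constant(-a.data.max(axis=axis, keepdims=True)))
    e = exp(shifted)
    return mul(e, power(tsum(e, axis=axis, keepdims=True), -1.0))


def custom_op(
    data: np.ndarray,
    parents: Tuple[Tensor, ...],
    backward: Callable[[np.ndarray], Sequence[Optional[np.ndarray]]],
) -> Tensor:
    """Wrap a fused forward result with a hand-written backward closure."""
    return Tensor(data, parents=parents, backward=backward)
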
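"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operation set needed to train the recurrent
knee-angle estimator: broadcast add/mul, (batched) matmul, tanh, sigmoid,
softmax, concatenation/stacking, axis sums, reshape, and a numerically
stable binary cross-entropy on logits.  Everything is float64 and
deterministic; there is no graph caching, each forward pass builds a fresh
tape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "const", "add", "sub", "mul", "matmul", "tanh", "sigmoid",
    "softmax", "concat", "stack", "tsum", "tmean", "reshape",
    "bce_with_logits", "square",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting expanded."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node on the tape: a float64 ndarray plus its backward closure."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad",
                 "_grad_owned")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._grad_owned = False

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def _accumulate(self, g: np.ndarray) -> None:
        # copy-on-write: most nodes receive exactly one contribution, so the
        # incoming array (never mutated by callers) is aliased until a second
        # contribution forces a fresh allocation
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self) -> None:
        """Reverse-accumulate gradients from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative topological sort (graphs are deep: ~140 recurrent steps)
        visiting: list[tuple[Tensor, int]] = [(self, 0)]
        while visiting:
            node, state = visiting.pop()
            if state == 0:
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                visiting.append((node, 1))
                for p in node._parents:
                    if p.requires_grad and id(p) not in seen:
                        visiting.append((p, 0))
            else:
                topo.append(node)
        del stack_
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def const(x) -> Tensor:
    """Wrap an array as a constant (no gradient) tensor."""
    return x if isinstance(x, Tensor) else Tensor(x)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- primitives -------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, (a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    out._backward = backward
    return out


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data - b.data, (a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.shape))

    out._backward = backward
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, (a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    out._backward = backward
    return out


def square(a) -> Tensor:
    return mul(a, a)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data @ b.data, (a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

    out._backward = backward
    return out


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    y = np.tanh(a.data)
    out = Tensor(y, (a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - y * y))

    out._backward = backward
    return out


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    y = _sigmoid(a.data)
    out = Tensor(y, (a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * y * (1.0 - y))

    out._backward = backward
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # branchless stable sigmoid
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, (a,))

    def backward(g):
        if a.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            a._accumulate(y * (g - dot))

    out._backward = backward
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out._backward = backward
    return out


def stack(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    out._backward = backward
    return out


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), (a,))

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).copy())
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

    out._backward = backward
    return out


def tmean(a) -> Tensor:
    a = _as_tensor(a)
    return mul(tsum(a), Tensor(1.0 / a.data.size))


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(a.data.reshape(shape), (a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    out._backward = backward
    return out


def bce_with_logits(logits, targets) -> Tensor:
    """Mean binary cross-entropy between sigmoid(logits) and targets in [0,1].

    Stable form: max(z,0) - z*y + log(1 + exp(-|z|)); gradient sigmoid(z)-y.
    """
    logits = _as_tensor(logits)
    y = np.asarray(targets, dtype=np.float64)
    z = logits.data
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean(), (logits,))

    def backward(g):
        if logits.requires_grad:
            logits._accumulate(g * (_sigmoid(z) - y) / z.size)

    out._backward = backward
    return out
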
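"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module provides exactly the primitives the message-passing models need:
dense affine maps, SELU / sigmoid / tanh nonlinearities, row gather and
segment-sum scatter (the two index operations that express neighbourhood
aggregation over batched graphs), a numerically stable binary cross-entropy
with logits, dropout, and the Adam optimizer.

All arithmetic is float64. Gradients are accumulated on a tape built during
the forward pass and replayed in reverse topological order by
:meth:`Tensor.backward`.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather_rows",
    "gather_flat",
    "segment_sum",
    "selu",
    "sigmoid",
    "tanh",
    "exp",
    "log",
    "dropout",
    "bce_with_logits",
    "Linear",
    "MLP",
    "GRUCell",
    "Adam",
]

# SELU constants from the self-normalizing network convention.
_SELU_ALPHA = 1.6732632423543772848170429916717
_SELU_LAMBDA = 1.0507009873554804934193349852946


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # Sum over leading axes that were added by broadcasting.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # Sum over axes that were broadcast from size 1.
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward: Callable | None = None):
        self.data = _as_array(data)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # ---- bookkeeping -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        """Reverse-accumulate gradients from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep graphs exceed recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data ** 2, other.data.shape))

        out._backward = bw
        return out

    def __matmul__(self, other):
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self):
        return self.sum() * (1.0 / self.data.size)


# ---- structural ops ------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    arrs = [t.data for t in tensors]
    out = Tensor(np.concatenate(arrs, axis=axis), _parents=tuple(tensors))
    sizes = [a.shape[axis] for a in arrs]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    out._backward = bw
    return out


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``x[index]``; backward scatter-adds into the source."""
    index = np.asarray(index, dtype=np.intp)
    out = Tensor(x.data[index], _parents=(x,))

    def bw(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, index, g)
        x._accumulate(acc)

    out._backward = bw
    return out


def gather_flat(x: Tensor, flat_index: np.ndarray) -> Tensor:
    """Select elements of the row-major flattened view of ``x`` (1-D output)."""
    flat_index = np.asarray(flat_index, dtype=np.intp)
    out = Tensor(x.data.ravel()[flat_index], _parents=(x,))

    def bw(g):
        acc = np.zeros(x.data.size)
        np.add.at(acc, flat_index, g)
        x._accumulate(acc.reshape(x.data.shape))

    out._backward = bw
    return out


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets; backward is a gather."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(data, segment_ids, x.data)
    out = Tensor(data, _parents=(x,))
    out._backward = lambda g: x._accumulate(g[segment_ids])
    return out


# ---- nonlinearities ------------------------------------------------------

def selu(x: Tensor) -> Tensor:
    pos = x.data > 0
    y = np.where(pos, _SELU_LAMBDA * x.data,
                 _SELU_LAMBDA * _SELU_ALPHA * np.expm1(x.data))
    out = Tensor(y, _parents=(x,))

    def bw(g):
        dx = np.where(pos, _SELU_LAMBDA,
                      _SELU_LAMBDA * _SELU_ALPHA * np.exp(x.data))
        x._accumulate(g * dx)

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = 0.5 * (1.0 + np.tanh(0.5 * x.data))  # stable logistic
    out = Tensor(y, _parents=(x,))
    out._backward = lambda g: x._accumulate(g * y * (1.0 - y))
    return out


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, _parents=(x,))
    out._backward = lambda g: x._accumulate(g * (1.0 - y * y))
    return out


def exp(x: Tensor) -> Tensor:
    y = np.exp(x.data)
    out = Tensor(y, _parents=(x,))
    out._backward = lambda g: x._accumulate(g * y)
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), _parents=(x,))
    out._backward = lambda g: x._accumulate(g / x.data)
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    keep = rng.random(x.data.shape) >= p
    scale = 1.0 / (1.0 - p)
    out = Tensor(x.data * keep * scale, _parents=(x,))
    out._backward = lambda g: x._accumulate(g * keep * scale)
    return out


def bce_with_logits(scores: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy on pre-sigmoid scores.

    Uses the standard stable form ``max(s,0) - s*y + log1p(exp(-|s|))``;
    the gradient is ``sigmoid(s) - y``.
    """
    s = scores.data
    y = _as_array(targets)
    loss = np.maximum(s, 0.0) - s * y + np.log1p(np.exp(-np.abs(s)))
    out = Tensor(loss, _parents=(scores,))

    def bw(g):
        p = 0.5 * (1.0 + np.tanh(0.5 * s))
        scores._accumulate(g * (p - y))

    out._backward = bw
    return out


# ---- layers --------------------------------------------------------------

def _lecun_normal(rng: np.random.Generator, fan_in: int, fan_out: int):
    # Self-normalizing initialization: weights ~ N(0, 1/fan_in).
    return rng.normal(0.0, math.sqrt(1.0 / fan_in), size=(fan_in, fan_out))


class Linear:
    """Affine map y = x W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(_lecun_normal(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP:
    """Feed-forward stack with SELU on every layer except (optionally) the last."""

    def __init__(self, widths: Sequence[int], rng: np.random.Generator,
                 final_activation: bool = False):
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        self.final_activation = final_activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1 or self.final_activation:
                x = selu(x)
        return x

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]


class GRUCell:
    """Gated recurrent unit; weights shared across nodes/edges and steps.

    z = sigmoid(x Wz + h Uz + bz)        update gate
    r = sigmoid(x Wr + h Ur + br)        reset gate
    n = tanh(x Wn + r * (h Un + bhn) + bn)
    h' = (1 - z) * n + z * h
    """

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator):
        def w(n_in, n_out):
            return Tensor(_lecun_normal(rng, n_in, n_out), requires_grad=True)

        self.Wz, self.Uz = w(input_size, hidden_size), w(hidden_size, hidden_size)
        self.Wr, self.Ur = w(input_size, hidden_size), w(hidden_size, hidden_size)
        self.Wn, self.Un = w(input_size, hidden_size), w(hidden_size, hidden_size)
        self.bz = Tensor(np.zeros(hidden_size), requires_grad=True)
        self.br = Tensor(np.zeros(hidden_size), requires_grad=True)
        self.bn = Tensor(np.zeros(hidden_size), requires_grad=True)
        self.bhn = Tensor(np.zeros(hidden_size), requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        z = sigmoid(x @ self.Wz + h @ self.Uz + self.bz)
        r = sigmoid(x @ self.Wr + h @ self.Ur + self.br)
        n = tanh(x @ self.Wn + r * (h @ self.Un + self.bhn) + self.bn)
        return (1.0 - z) * n + z * h

    def parameters(self) -> list[Tensor]:
        return [self.Wz, self.Uz, self.Wr, self.Ur, self.Wn, self.Un,
                self.bz, self.br, self.bn, self.bhn]


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

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
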
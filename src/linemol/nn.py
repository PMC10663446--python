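"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A small tensor-autograd core: a :class:`Tensor` wraps a float64 ndarray,
records the operation that produced it, and `backward()` runs reverse-mode
accumulation over the topologically sorted graph.  Only the operations the
encoder and its training objectives need are provided — matrix products,
broadcasting arithmetic, reductions, softmax/log-softmax, the exact
(Gaussian-CDF) GELU, layer normalisation, indexed gathers and concatenation —
plus an Adam optimiser with decoupled weight decay and per-group learning
rates.  Gradient correctness of every primitive is checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "stack_rows", "dropout", "trunc_normal", "Adam"]

_SQRT1_2 = 1.0 / math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- plumbing ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            # copy: g may be a view into (or alias of) an upstream buffer
            self.grad = np.array(g, dtype=np.float64)
            if self.grad.shape != self.data.shape:  # scalar broadcast
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs exceed the recursion limit
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:       # dot product -> scalar
                ga, gb = g * b, g * a
            elif a.ndim == 1:                     # [k] @ [k,n] -> [n]
                ga, gb = b @ g, np.outer(a, g)
            elif b.ndim == 1:                     # [m,k] @ [k] -> [m]
                ga, gb = np.outer(g, b), a.T @ g
            else:
                ga = g @ b.swapaxes(-1, -2)
                gb = a.swapaxes(-1, -2) @ g
            if self.requires_grad:
                self._accum(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(gb, b.shape))

        out._backward = backward
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = backward
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.T)

        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = backward
        return out

    def take_rows(self, index: np.ndarray):
        """Gather rows by an integer index array (first axis)."""
        index = np.asarray(index, dtype=np.intp)
        out = Tensor(self.data[index], _prev=(self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, index, g)
                self._accum(full)

        out._backward = backward
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out.data)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = backward
        return out

    def gelu(self):
        """Exact GELU: x * Phi(x) with the Gaussian CDF."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x * _SQRT1_2))
        out = Tensor(x * phi, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
                self._accum(g * (phi + x * pdf))

        out._backward = backward
        return out

    def sigmoid(self):
        s = np.where(self.data >= 0,
                     1.0 / (1.0 + np.exp(-np.abs(self.data))),
                     np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))))
        out = Tensor(s, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = backward
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                inner = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - inner))

        out._backward = backward
        return out

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        out = Tensor(ls, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g - np.exp(ls) * g.sum(axis=axis, keepdims=True))

        out._backward = backward
        return out

    def softplus(self):
        """log(1 + exp(x)) computed stably; gradient is sigmoid(x)."""
        x = self.data
        out = Tensor(np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x))), _prev=(self,))

        def backward(g):
            if self.requires_grad:
                s = np.where(x >= 0,
                             1.0 / (1.0 + np.exp(-np.abs(x))),
                             np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
                self._accum(g * s)

        out._backward = backward
        return out

    def sqrt(self):
        return self ** 0.5

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Row-wise layer normalisation with affine parameters (last axis)."""
        mu = self.mean(axis=-1, keepdims=True)
        centered = self - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered * (var + eps) ** -0.5
        return normed * gamma + beta


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = backward
    return out


def stack_rows(tensors: Sequence[Tensor]) -> Tensor:
    """Stack 1-D tensors into a 2-D matrix (axis 0)."""
    tensors = list(tensors)
    out = Tensor(np.stack([t.data for t in tensors]), _prev=tuple(tensors))

    def backward(g):
        for k, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(g[k])

    out._backward = backward
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= rate).astype(np.float64) / (1.0 - rate)
    return x * Tensor(keep)


def trunc_normal(shape, std: float, rng: np.random.Generator) -> np.ndarray:
    """Normal(0, std) samples truncated (clipped) at two standard deviations."""
    return np.clip(rng.standard_normal(shape) * std, -2.0 * std, 2.0 * std)


class Adam:
    """Adam with decoupled weight decay and optional per-group learning rates.

    ``groups`` is a list of (name->Tensor dict, learning-rate) pairs; a plain
    dict of parameters forms a single group at the base learning rate.
    """

    def __init__(self, params, lr: float = 2e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-6):
        if isinstance(params, dict):
            groups = [(params, lr)]
        else:
            groups = [(dict(p), g_lr) for p, g_lr in params]
        self.groups = groups
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.lr_scale = 1.0
        self._m = {}
        self._v = {}
        for params_g, _ in self.groups:
            for name, p in params_g.items():
                self._m[name] = np.zeros_like(p.data)
                self._v[name] = np.zeros_like(p.data)

    def zero_grad(self):
        for params_g, _ in self.groups:
            for p in params_g.values():
                p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for params_g, lr in self.groups:
            lr = lr * self.lr_scale
            for name, p in params_g.items():
                if p.grad is None:
                    continue
                m = self._m[name]
                v = self._v[name]
                m *= self.b1
                m += (1.0 - self.b1) * p.grad
                v *= self.b2
                v += (1.0 - self.b2) * p.grad * p.grad
                update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                if self.weight_decay:
                    update = update + self.weight_decay * p.data
                p.data -= lr * update
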
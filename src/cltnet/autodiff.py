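"""Reverse-mode automatic differentiation over NumPy arrays.

A small tape-based engine sufficient for the network in :mod:`cltnet.model`:
broadcasting arithmetic, (batched) matrix products, the elementwise
nonlinearities the architecture needs (sigmoid, tanh, ELU, erf for the exact
GELU), reductions, shape ops, padding/slicing for convolutions, stable
softmax / log-softmax, and a fused softmax-cross-entropy head.

All data is kept in float64. Gradients accumulate into ``Tensor.grad``;
``Tensor.backward()`` runs a topological sweep over the recorded graph.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy import special

__all__ = ["Tensor", "cat", "cross_entropy_logits", "Adam"]


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _acc(t: "Tensor", g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- introspection ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        o = _as_tensor(other)

        def bw(g):
            _acc(self, _unbroadcast(g, self.shape))
            _acc(o, _unbroadcast(g, o.shape))

        return _make(self.data + o.data, (self, o), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            _acc(self, -g)

        return _make(-self.data, (self,), bw)

    def __sub__(self, other):
        o = _as_tensor(other)

        def bw(g):
            _acc(self, _unbroadcast(g, self.shape))
            _acc(o, _unbroadcast(-g, o.shape))

        return _make(self.data - o.data, (self, o), bw)

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        o = _as_tensor(other)

        def bw(g):
            _acc(self, _unbroadcast(g * o.data, self.shape))
            _acc(o, _unbroadcast(g * self.data, o.shape))

        return _make(self.data * o.data, (self, o), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = _as_tensor(other)

        def bw(g):
            _acc(self, _unbroadcast(g / o.data, self.shape))
            _acc(o, _unbroadcast(-g * self.data / (o.data ** 2), o.shape))

        return _make(self.data / o.data, (self, o), bw)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, c: float):
        if not np.isscalar(c):
            raise TypeError("only scalar exponents are supported")

        def bw(g):
            _acc(self, g * c * self.data ** (c - 1))

        return _make(self.data ** c, (self,), bw)

    def __matmul__(self, other):
        o = _as_tensor(other)

        def bw(g):
            if self.requires_grad:
                _acc(self, _unbroadcast(g @ np.swapaxes(o.data, -1, -2), self.shape))
            if o.requires_grad:
                _acc(o, _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, o.shape))

        return _make(self.data @ o.data, (self, o), bw)

    # -- elementwise functions ----------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            _acc(self, g * out_data)

        return _make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            _acc(self, g / self.data)

        return _make(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            _acc(self, g * (1.0 - out_data ** 2))

        return _make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = special.expit(self.data)

        def bw(g):
            _acc(self, g * out_data * (1.0 - out_data))

        return _make(out_data, (self,), bw)

    def erf(self):
        def bw(g):
            _acc(self, g * (2.0 / np.sqrt(np.pi)) * np.exp(-self.data ** 2))

        return _make(special.erf(self.data), (self,), bw)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * np.expm1(self.data))

        def bw(g):
            _acc(self, g * np.where(pos, 1.0, out_data + alpha))

        return _make(out_data, (self,), bw)

    def gelu(self):
        """Exact Gaussian Error Linear Unit: x * Phi(x) via the error function."""
        phi = 0.5 * (1.0 + special.erf(self.data / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * self.data ** 2) / np.sqrt(2.0 * np.pi)

        def bw(g):
            _acc(self, g * (phi + self.data * pdf))

        return _make(self.data * phi, (self,), bw)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                axes = (axis,) if np.isscalar(axis) else tuple(axis)
                axes = tuple(a % self.data.ndim for a in axes)
                for a in sorted(axes):
                    gg = np.expand_dims(gg, a)
            _acc(self, np.broadcast_to(gg, self.data.shape).copy())

        return _make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g):
            _acc(self, g.reshape(self.data.shape))

        return _make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            _acc(self, g.transpose(inv))

        return _make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, key):
        def bw(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, key, g)
            _acc(self, buf)

        return _make(self.data[key], (self,), bw)

    def pad_last(self, left: int, right: int):
        """Zero-pad the last axis (used for 'same' temporal convolutions)."""
        width = [(0, 0)] * (self.data.ndim - 1) + [(left, right)]
        T = self.data.shape[-1]

        def bw(g):
            _acc(self, g[..., left:left + T])

        return _make(np.pad(self.data, width), (self,), bw)

    # -- softmax family -----------------------------------------------------
    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            _acc(self, out_data * (g - dot))

        return _make(out_data, (self,), bw)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse

        def bw(g):
            _acc(self, g - np.exp(out_data) * g.sum(axis=axis, keepdims=True))

        return _make(out_data, (self,), bw)

    # -- graph traversal -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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

        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def cat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _acc(t, g[tuple(idx)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean multinomial cross-entropy of a logit batch, fused with softmax.

    Equivalent to ``-mean(log_softmax(logits)[i, labels[i]])``; the fused
    backward pass ``(softmax - onehot)/M`` is used for numerical robustness.
    """
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    M = logp.shape[0]
    val = -logp[np.arange(M), labels].mean()

    def bw(g):
        gi = np.exp(logp)
        gi[np.arange(M), labels] -= 1.0
        _acc(logits, g * gi / M)

    return _make(np.asarray(val), (logits,), bw)


class Adam:
    """Adam optimizer with the standard defaults (no weight decay, no schedule)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
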
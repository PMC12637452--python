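"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the vision/temporal transformers in this
package need: broadcasting arithmetic, batched matmul, reshape/transpose,
row gathering, concatenation, reductions, GELU, fused softmax / layer-norm /
cross-entropy. Gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward`, which walks the recorded graph in reverse
topological order. Every op is checked against central finite differences in
the test suite.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "gather_rows", "cross_entropy", "layer_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        # Takes ownership of ``g``: backward closures hand over fresh arrays
        # (or disjoint/dead views), copying only when two parents would
        # otherwise share one buffer.
        if self.grad is None:
            if g.dtype != self.data.dtype:
                g = g.astype(self.data.dtype)
            self.grad = g
        else:
            self.grad += g

    @staticmethod
    def _node(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        rg = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=rg)
        if rg:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def bwd(g):
            ga = _unbroadcast(g, self.data.shape) if self.requires_grad else None
            if other.requires_grad:
                gb = _unbroadcast(g, other.data.shape)
                if gb is ga:  # same buffer for both parents: decouple
                    gb = gb.copy()
                other._accum(gb)
            if ga is not None:
                self._accum(ga)

        return self._node(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return self._node(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._node(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other.pow(-1.0)
        return self * (1.0 / other)

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent

        def bwd(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        return self._node(out_data, (self,), bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out_data = np.matmul(self.data, other.data)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._node(out_data, (self, other), bwd)

    __matmul__ = matmul

    # -- shape ops --------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._node(out_data, (self,), bwd)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._node(out_data, (self,), bwd)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]
        fancy = any(
            isinstance(i, (np.ndarray, list))
            for i in (idx if isinstance(idx, tuple) else (idx,))
        )

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if fancy:  # may contain duplicate indices
                    np.add.at(full, idx, g)
                else:
                    full[idx] += g
                self._accum(full)

        return self._node(out_data, (self,), bwd)

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._node(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ---------------------------------------------------

    def gelu(self) -> "Tensor":
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        out_data = x * cdf

        def bwd(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
                self._accum(g * (cdf + x * pdf))

        return self._node(out_data.astype(x.dtype), (self,), bwd)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if self.requires_grad:
                inner = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - inner))

        return self._node(s, (self,), bwd)


# -- free functions -------------------------------------------------------


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._node(out_data, tensors, bwd)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows along axis 1: ``x`` (B, T, D), ``idx`` (B, K) -> (B, K, D).

    Indices must be unique within each batch row (they are permutations or
    sub-permutations in every use here), so the backward scatter need not
    accumulate duplicates.
    """
    idx = np.asarray(idx)
    idx_e = np.broadcast_to(idx[:, :, None], idx.shape + (x.data.shape[-1],))
    out_data = np.take_along_axis(x.data, idx_e, axis=1)

    def bwd(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.put_along_axis(full, idx_e, g, axis=1)
            x._accum(full)

    return Tensor._node(out_data, (x,), bwd)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalization over the last axis, fused forward/backward."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gamma.data + beta.data

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum(
                (g * xhat).sum(axis=tuple(range(g.ndim - 1)))
            )
        if beta.requires_grad:
            beta._accum(g.sum(axis=tuple(range(g.ndim - 1))))
        if x.requires_grad:
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv * (dxhat - m1 - xhat * m2))

    return Tensor._node(out_data.astype(x.data.dtype), (x, gamma, beta), bwd)


def cross_entropy(
    logits: Tensor,
    labels: np.ndarray,
    class_weights: np.ndarray | None = None,
    reduction: str = "mean",
) -> Tensor:
    """Class-weighted cross entropy on (N, C) logits with integer labels.

    With ``reduction='mean'`` the weighted losses are divided by the sum of
    the per-sample weights (so unweighted reduces to the plain mean); with
    ``'sum_over'`` a caller-provided divisor can be emulated by scaling the
    returned value.
    """
    labels = np.asarray(labels)
    n, c = logits.data.shape
    shifted = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(shifted).sum(axis=1)) + logits.data.max(axis=1)
    picked = logits.data[np.arange(n), labels]
    losses = logsumexp - picked
    if class_weights is None:
        w = np.ones(n, dtype=logits.data.dtype)
    else:
        w = np.asarray(class_weights, dtype=logits.data.dtype)[labels]
    if reduction == "mean":
        denom = w.sum()
    elif reduction == "sum":
        denom = 1.0
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    out_data = np.asarray((losses * w).sum() / denom, dtype=logits.data.dtype)

    softmax = np.exp(shifted)
    softmax /= softmax.sum(axis=1, keepdims=True)

    def bwd(g):
        if logits.requires_grad:
            grad = softmax.copy()
            grad[np.arange(n), labels] -= 1.0
            grad *= (w / denom)[:, None]
            logits._accum(g * grad)

    return Tensor._node(out_data, (logits,), bwd)
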
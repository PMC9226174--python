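"""Compact reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operator set the cell-graph networks need: dense and
sparse-constant matrix products, broadcast add/multiply, ReLU/tanh, row
gather, per-graph segment mean/max, concatenation and a fused
softmax-cross-entropy loss.  Gradients are accumulated by topological-order
backpropagation; sparse adjacency matrices are treated as constants (no
gradient flows into graph structure).
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad down to ``shape`` to undo numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    def __mul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), bwd)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bwd)

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data**exponent

        def bwd(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), bwd)

    def sum(self) -> "Tensor":
        def bwd(g):
            self._accum(np.full_like(self.data, float(g)))

        return Tensor._make(self.data.sum(), (self,), bwd)

    # -- structured ops ----------------------------------------------------
    def gather_rows(self, index: np.ndarray) -> "Tensor":
        index = np.asarray(index, dtype=int)

        def bwd(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, index, g)
            self._accum(acc)

        return Tensor._make(self.data[index], (self,), bwd)

    def concat_cols(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        k = self.data.shape[1]

        def bwd(g):
            if self.requires_grad:
                self._accum(g[:, :k])
            if other.requires_grad:
                other._accum(g[:, k:])

        return Tensor._make(np.hstack([self.data, other.data]), (self, other), bwd)


def spmm(sparse_const, x: Tensor) -> Tensor:
    """Product of a constant scipy sparse matrix with a Tensor (no grad into A)."""

    def bwd(g):
        x._accum(sparse_const.T @ g)

    return Tensor._make(sparse_const @ x.data, (x,), bwd)


def segment_mean(x: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Per-segment mean of rows; empty segments yield zero rows."""
    segments = np.asarray(segments, dtype=int)
    counts = np.bincount(segments, minlength=n_segments).astype(float)
    safe = np.maximum(counts, 1.0)
    sums = np.zeros((n_segments, x.data.shape[1]))
    np.add.at(sums, segments, x.data)

    def bwd(g):
        x._accum((g / safe[:, None])[segments])

    return Tensor._make(sums / safe[:, None], (x,), bwd)


def segment_max(x: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Per-segment max of rows; empty segments yield zero rows.

    The gradient is split equally among rows attaining the maximum (a valid
    subgradient under ties).
    """
    segments = np.asarray(segments, dtype=int)
    d = x.data.shape[1]
    out = np.full((n_segments, d), -np.inf)
    np.maximum.at(out, segments, x.data)
    empty = ~np.isin(np.arange(n_segments), segments)
    out[empty] = 0.0
    hit = x.data == out[segments]
    ties = np.zeros((n_segments, d))
    np.add.at(ties, segments, hit)
    ties = np.maximum(ties, 1.0)

    def bwd(g):
        x._accum(hit * (g / ties)[segments])

    return Tensor._make(out, (x,), bwd)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray):
    """Mean cross-entropy over rows; returns (loss Tensor, probabilities array)."""
    labels = np.asarray(labels, dtype=int)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    nll = -np.log(np.maximum(probs[np.arange(n), labels], 1e-300)).mean()

    def bwd(g):
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accum(float(g) * grad / n)

    return Tensor._make(nll, (logits,), bwd), probs


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)
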
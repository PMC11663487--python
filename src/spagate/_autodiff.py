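"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the graph attention auto-encoder and its
losses need: dense linear algebra, elementwise nonlinearities, row
gathering, per-row (segment) softmax over an edge list, and sparse
attention-weighted neighbor aggregation.  Gradients are accumulated by a
topological-order backward sweep, the same contract as the mainstream
autodiff frameworks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "matmul",
    "gather_rows",
    "segment_softmax",
    "EdgeIndex",
    "edge_aggregate",
    "sigmoid",
    "elu",
    "relu",
    "leaky_relu",
    "log",
    "exp",
    "sqrt",
    "clip_min",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        out = _make(self.data.T, (self,))
        if out.requires_grad:
            def _bwd(g):
                return (g.T,)
            out._backward = _bwd
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            a_shape, b_shape = self.data.shape, other.data.shape
            out._backward = lambda g: (_unbroadcast(g, a_shape), _unbroadcast(g, b_shape))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            a, b = self, other
            out._backward = lambda g: (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            a, b = self, other
            out._backward = lambda g: (
                _unbroadcast(g / b.data, a.data.shape),
                _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape),
            )
        return out

    def __pow__(self, p: float):
        out = _make(self.data ** p, (self,))
        if out.requires_grad:
            a = self
            out._backward = lambda g: (g * p * a.data ** (p - 1),)
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            shape = self.data.shape

            def _bwd(g):
                g = np.asarray(g)
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                return (np.broadcast_to(g, shape).copy(),)

            out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = _make(self.data.reshape(*shape), (self,))
        if out.requires_grad:
            orig = self.data.shape
            out._backward = lambda g: (g.reshape(orig),)
        return out

    # -- backward sweep -------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.array(g, dtype=np.float64)
                else:
                    parent.grad += g

    def zero_grad(self):
        self.grad = None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = parents
    return out


# ----------------------------------------------------------------------
# functional ops
# ----------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = _make(a.data @ b.data, (a, b))
    if out.requires_grad:
        out._backward = lambda g: (g @ b.data.T, a.data.T @ g)
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``x[idx]`` with gradient scatter-add on the backward pass."""
    x = _as_tensor(x)
    idx = np.asarray(idx, dtype=np.intp)
    out = _make(x.data[idx], (x,))
    if out.requires_grad:
        shape = x.data.shape

        def _bwd(g):
            gx = np.zeros(shape, dtype=np.float64)
            np.add.at(gx, idx, g)
            return (gx,)

        out._backward = _bwd
    return out


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of a flat score vector within groups sharing a segment id.

    Used to normalize attention logits over each spot's neighbor set.
    Segments are the edge-list row indices; every group with at least one
    member sums to exactly 1.
    """
    scores = _as_tensor(scores)
    seg = np.asarray(segment_ids, dtype=np.intp)
    s = scores.data
    # numerically stable: subtract the per-segment max
    seg_max = np.full(n_segments, -np.inf)
    np.maximum.at(seg_max, seg, s)
    e = np.exp(s - seg_max[seg])
    denom = np.bincount(seg, weights=e, minlength=n_segments)
    y = e / denom[seg]
    out = _make(y, (scores,))
    if out.requires_grad:
        def _bwd(g):
            # d s_e = y_e * (g_e - sum_{e' in seg} y_e' g_e')
            dot = np.bincount(seg, weights=y * g, minlength=n_segments)
            return (y * (g - dot[seg]),)

        out._backward = _bwd
    return out


class EdgeIndex:
    """Precomputed CSR structure for a fixed directed edge list.

    Built once per graph; lets :func:`edge_aggregate` run as two sparse
    matrix products instead of scatter-adds.  Edges must be sorted by
    (row, col).
    """

    __slots__ = ("rows", "cols", "n", "indptr", "tperm", "tindptr")

    def __init__(self, rows: np.ndarray, cols: np.ndarray, n: int):
        self.rows = np.asarray(rows, dtype=np.int32)
        self.cols = np.asarray(cols, dtype=np.int32)
        self.n = int(n)
        counts = np.bincount(self.rows, minlength=n)
        self.indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int32)
        self.tperm = np.lexsort((self.rows, self.cols))
        tcounts = np.bincount(self.cols, minlength=n)
        self.tindptr = np.concatenate([[0], np.cumsum(tcounts)]).astype(np.int32)

    @property
    def n_edges(self) -> int:
        return len(self.rows)


def edge_aggregate(attn: Tensor, feats: Tensor, edges: EdgeIndex) -> Tensor:
    """out[i] = sum over edges e with rows[e]==i of attn[e] * feats[cols[e]].

    The sparse message-passing primitive of the attention layers.
    """
    import scipy.sparse as sp

    attn, feats = _as_tensor(attn), _as_tensor(feats)
    a_csr = sp.csr_matrix((attn.data, edges.cols, edges.indptr),
                          shape=(edges.n, edges.n))
    agg = a_csr @ feats.data
    out = _make(agg, (attn, feats))
    if out.requires_grad:
        def _bwd(g):
            g_rows = g[edges.rows]
            d_attn = np.einsum("ef,ef->e", g_rows, feats.data[edges.cols])
            at_csr = sp.csr_matrix((attn.data[edges.tperm], edges.rows[edges.tperm],
                                    edges.tindptr), shape=(edges.n, edges.n))
            d_feats = at_csr @ g
            return (d_attn, d_feats)

        out._backward = _bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    y = np.empty_like(x.data)
    pos = x.data >= 0
    y[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    y[~pos] = ex / (1.0 + ex)
    out = _make(y, (x,))
    if out.requires_grad:
        out._backward = lambda g: (g * y * (1.0 - y),)
    return out


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    x = _as_tensor(x)
    neg = x.data < 0
    y = np.where(neg, alpha * np.expm1(x.data), x.data)
    out = _make(y, (x,))
    if out.requires_grad:
        dy = np.where(neg, y + alpha, 1.0)
        out._backward = lambda g: (g * dy,)
    return out


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out = _make(np.maximum(x.data, 0.0), (x,))
    if out.requires_grad:
        mask = (x.data > 0).astype(np.float64)
        out._backward = lambda g: (g * mask,)
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    x = _as_tensor(x)
    out = _make(np.where(x.data > 0, x.data, slope * x.data), (x,))
    if out.requires_grad:
        dy = np.where(x.data > 0, 1.0, slope)
        out._backward = lambda g: (g * dy,)
    return out


def log(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out = _make(np.log(x.data), (x,))
    if out.requires_grad:
        out._backward = lambda g: (g / x.data,)
    return out


def exp(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    y = np.exp(x.data)
    out = _make(y, (x,))
    if out.requires_grad:
        out._backward = lambda g: (g * y,)
    return out


def sqrt(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    y = np.sqrt(x.data)
    out = _make(y, (x,))
    if out.requires_grad:
        out._backward = lambda g: (g * 0.5 / y,)
    return out


def clip_min(x: Tensor, lo: float) -> Tensor:
    """max(x, lo); gradient passes through only where x > lo."""
    x = _as_tensor(x)
    out = _make(np.maximum(x.data, lo), (x,))
    if out.requires_grad:
        mask = (x.data > lo).astype(np.float64)
        out._backward = lambda g: (g * mask,)
    return out
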
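"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` accumulates gradients by reverse topological
traversal.  The op set is deliberately small — exactly what the dense blocks,
GRU cells and graph-attention layers in :mod:`zindelta.nn` need — and every
op supports numpy broadcasting with correct gradient reduction.

Segment operations (:func:`segment_sum`, :func:`segment_softmax`) aggregate
edge- or atom-level rows into per-node or per-molecule rows, which is how
variable-size molecular graphs are batched without padding.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "segment_sum",
    "segment_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(grad, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(grad, b.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad, a=self):
            if a.requires_grad:
                a._accum(-grad)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(grad * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(grad * a.data, b.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(grad / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-grad * a.data / (b.data**2), b.shape))

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        def backward(grad, a=self, p=exponent):
            if a.requires_grad:
                a._accum(grad * p * a.data ** (p - 1))

        return Tensor._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accum(grad @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ grad)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(grad, a=self, o=out_data):
            if a.requires_grad:
                a._accum(grad * o)

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(grad, a=self, o=out_data):
            if a.requires_grad:
                a._accum(grad * (1.0 - o**2))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def backward(grad, a=self, o=out_data):
            if a.requires_grad:
                a._accum(grad * o * (1.0 - o))

        return Tensor._make(out_data, (self,), backward)

    def leaky_relu(self, alpha: float = 0.01):
        mask = np.where(self.data > 0, 1.0, alpha)

        def backward(grad, a=self, m=mask):
            if a.requires_grad:
                a._accum(grad * m)

        return Tensor._make(self.data * mask, (self,), backward)

    def elu(self, alpha: float = 1.0):
        neg = self.data <= 0
        out_data = np.where(neg, alpha * np.expm1(self.data), self.data)

        def backward(grad, a=self, o=out_data, n=neg, al=alpha):
            if a.requires_grad:
                a._accum(grad * np.where(n, o + al, 1.0))

        return Tensor._make(out_data, (self,), backward)

    def softplus(self):
        # numerically stable log(1 + e^x)
        out_data = np.logaddexp(0.0, self.data)
        sig = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def backward(grad, a=self, s=sig):
            if a.requires_grad:
                a._accum(grad * s)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions / reshaping -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad, a=self, ax=axis, kd=keepdims):
            if a.requires_grad:
                g = np.asarray(grad)
                if ax is not None and not kd:
                    g = np.expand_dims(g, ax)
                a._accum(np.broadcast_to(g, a.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(grad, a=self, s=old):
            if a.requires_grad:
                a._accum(grad.reshape(s))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, idx):
        """Row gather; ``idx`` is an integer array (or slice)."""

        def backward(grad, a=self, i=idx):
            if a.requires_grad:
                g = np.zeros_like(a.data)
                np.add.at(g, i, grad)
                a._accum(g)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- backward pass ---------------------------------------------------------
    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; recursion overflows on deep graphs
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad, ts=tensors, off=offsets, ax=axis):
        for t, a, b in zip(ts, off[:-1], off[1:]):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[ax] = slice(a, b)
                t._accum(grad[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets given per-row ids."""
    segment_ids = np.asarray(segment_ids)
    out_data = np.zeros((num_segments,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, segment_ids, t.data)

    def backward(grad, a=t, ids=segment_ids):
        if a.requires_grad:
            a._accum(grad[ids])

    return Tensor._make(out_data, (t,), backward)


def segment_softmax(logits: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of per-row logits normalised within each segment.

    ``logits`` has shape (n_rows, 1).  The per-segment max used for numerical
    stability is treated as a constant (its subgradient contribution cancels).
    """
    segment_ids = np.asarray(segment_ids)
    seg_max = np.full((num_segments,) + logits.data.shape[1:], -np.inf)
    np.maximum.at(seg_max, segment_ids, logits.data)
    shifted = logits - Tensor(seg_max[segment_ids])
    e = shifted.exp()
    denom = segment_sum(e, segment_ids, num_segments)
    return e / denom[segment_ids]
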
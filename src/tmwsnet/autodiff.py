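"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation network in this package is trained on CPU, so instead of a
heavyweight deep-learning framework it uses this small vectorised tape-based
engine: a :class:`Tensor` wraps an ``ndarray`` and records the operations
applied to it; :meth:`Tensor.backward` walks the tape in reverse topological
order accumulating gradients.  Only the operations the network actually needs
are implemented (broadcasting arithmetic, matmul, reductions, indexing,
concatenation, the usual activations, and segment max/mean pooling over voxel
partitions).  Gradients are checked against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concatenate", "segment_max", "segment_sum"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float64, copy=False)
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = tuple(_prev)
        self._backward = _backward

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._prev))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for child in it:
                    if id(child) not in seen and child.requires_grad:
                        seen.add(id(child))
                        stack.append((child, iter(child._prev)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accum(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 1:
                    ga = g[..., None] * b if a.ndim > 1 else g * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accum(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g) if b.ndim > 1 else a * g
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accum(_unbroadcast(gb, b.shape))

        out._backward = bw
        return out

    # -- elementwise functions ---------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * (1.0 - out.data ** 2)
        )
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * s * (1 - s))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    def silu(self):
        """x * sigmoid(x) (the SiLU / swish activation)."""
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * (s + self.data * s * (1 - s))
        )
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; ties route the gradient to the first maximiser."""
        idx = np.argmax(self.data, axis=axis)
        val = np.max(self.data, axis=axis, keepdims=keepdims)
        out = Tensor(val, _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            gg = g if not keepdims else np.squeeze(g, axis=axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(
                full, np.expand_dims(idx, axis), np.expand_dims(gg, axis), axis
            )
            self._accum(full)

        out._backward = bw
        return out

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.data.shape)
        )
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        inv = np.argsort(axes) if axes else None
        out._backward = lambda g: self.requires_grad and self._accum(
            g.transpose(inv) if inv is not None else g.transpose()
        )
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    # -- composed helpers ------------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))

        out._backward = bw
        return out

    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        ls = shifted - lse
        out = Tensor(ls, _prev=(self,))
        soft = np.exp(ls)

        def bw(g):
            if not self.requires_grad:
                return
            self._accum(g - soft * g.sum(axis=axis, keepdims=True))

        out._backward = bw
        return out


class Parameter(Tensor):
    """A trainable tensor (requires_grad always true)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def segment_sum(x: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    """Sum rows of ``x`` (S×c) into ``n_seg`` buckets given by ``seg`` (S ints)."""
    data = np.zeros((n_seg,) + x.data.shape[1:])
    np.add.at(data, seg, x.data)
    out = Tensor(data, _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g[seg])
    return out


def segment_max(x: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    """Per-bucket elementwise max of rows of a 2-D ``x``; every bucket must be hit.

    The gradient flows to the lowest-index row achieving the bucket maximum
    (deterministic tie-break).
    """
    S, c = x.data.shape
    rows = np.arange(S)
    winner = np.empty((n_seg, c), dtype=np.int64)
    for j in range(c):
        # within each bucket: descending value, ties by ascending row index
        order = np.lexsort((rows, -x.data[:, j], seg))
        seg_sorted = seg[order]
        first = np.ones(S, dtype=bool)
        first[1:] = seg_sorted[1:] != seg_sorted[:-1]
        winner[seg_sorted[first], j] = order[first]
    cols = np.broadcast_to(np.arange(c), (n_seg, c))
    data = x.data[winner, cols]
    out = Tensor(data, _prev=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        full = np.zeros_like(x.data)
        np.add.at(full, (winner.ravel(), cols.ravel()), g.ravel())
        x._accum(full)

    out._backward = bw
    return out
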
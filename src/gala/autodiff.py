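"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training objective mixes graph convolutions, attention softmaxes, a
gradient-reversed adversarial branch and a contrastive term, so analytic
gradients are obtained by taping elementary operations and replaying the
tape backwards. Only the operations actually used by the model are
implemented; all data is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concat", "stack", "grad_reverse", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry.

    Gradients accumulate in ``.grad`` for every tensor reachable from the
    loss whose ``requires_grad`` flag is set (parameters *and*
    intermediates, which Grad-CAM relies on).
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of self w.r.t. every requires_grad ancestor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative topological sort (graphs can be deep for long proteins)
        visiting: list[tuple[Tensor, bool]] = [(self, False)]
        while visiting:
            node, processed = visiting.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            visiting.append((node, True))
            for p in node._parents:
                visiting.append((p, False))
        del stack
        self.grad = np.asarray(grad, dtype=np.float64) if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(g, other.data.shape))
        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, -g)
        return out

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            _accum(self, _unbroadcast(g * other.data, self.data.shape))
            _accum(other, _unbroadcast(g * self.data, other.data.shape))
        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = tensor(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            _accum(self, _unbroadcast(g / other.data, self.data.shape))
            _accum(other, _unbroadcast(-g * self.data / other.data ** 2, other.data.shape))
        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 2:      # (k,) @ (k,n) -> (n,)
                _accum(self, g @ b.T)
                _accum(other, np.outer(a, g))
            elif a.ndim == 2 and b.ndim == 1:    # (m,k) @ (k,) -> (m,)
                _accum(self, np.outer(g, b))
                _accum(other, a.T @ g)
            elif a.ndim == 1 and b.ndim == 1:    # dot product
                _accum(self, g * b)
                _accum(other, g * a)
            else:
                _accum(self, g @ b.T)
                _accum(other, a.T @ g)
        out._backward = _bw
        return out

    # ------------------------------------------------------------ elementwise
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, g / self.data)
        return out

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, g * mask)
        return out

    def sigmoid(self):
        with np.errstate(over="ignore"):  # exp overflow saturates correctly
            val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, g * val * (1.0 - val))
        return out

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes only through the un-clipped region."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, g * mask)
        return out

    # -------------------------------------------------------------- reduction
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def _bw(g):
            if axis is None:
                _accum(self, np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                _accum(self, np.broadcast_to(g, self.data.shape).copy())
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # ------------------------------------------------------------------ shape
    @property
    def T(self):
        out = Tensor(self.data.T, self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, g.T)
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, g.reshape(self.data.shape))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def _bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            _accum(self, full)
        out._backward = _bw
        return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    t.grad = g.copy() if t.grad is None else t.grad + g


def tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)
    out._backward = _bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))

    def _bw(g):
        for i, t in enumerate(tensors):
            _accum(t, np.take(g, i, axis=axis))
    out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; the max shift is treated as a constant."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def grad_reverse(x: Tensor, lam: float = 1.0) -> Tensor:
    """Identity in the forward pass; multiplies the gradient by -lam."""
    out = Tensor(x.data, x.requires_grad, (x,))
    out._backward = lambda g: _accum(x, -lam * g)
    return out
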
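"""Reverse-mode automatic differentiation on NumPy arrays.

A minimal tape-based engine covering exactly the operations the message-passing
model needs: dense linear maps, elementwise arithmetic with broadcasting,
pointwise nonlinearities, concatenation, row gather and segment reduction over
directed-edge lists. All computation is float64.

Gradient correctness is exercised end-to-end by the finite-difference checks in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "matmul",
    "concat",
    "gather_rows",
    "segment_sum",
    "leaky_relu",
    "relu",
    "sigmoid",
    "tanh",
    "identity",
    "exp",
    "rowsum",
    "sum_all",
    "ACTIVATIONS",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node on the differentiation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this node (scalar unless `grad` is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ------------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def back(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def back(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _node(self.data / other.data, (self, other))

        def back(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        out._backward = back
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _node(a.data @ b.data, (a, b))

    def back(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    out._backward = back
    return out


def concat(tensors: list, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    out._backward = back
    return out


def _scatter_add_rows(values: np.ndarray, index: np.ndarray, n_rows: int) -> np.ndarray:
    """Row-wise scatter-add via bincount (much faster than np.add.at)."""
    if values.ndim == 1:
        return np.bincount(index, weights=values, minlength=n_rows)
    n_cols = values.shape[1]
    flat = (index[:, None] * n_cols + np.arange(n_cols)).ravel()
    return np.bincount(flat, weights=values.ravel(), minlength=n_rows * n_cols).reshape(
        n_rows, n_cols
    )


def gather_rows(t: Tensor, index: np.ndarray) -> Tensor:
    """Select rows `t[index]`; gradient scatters back with accumulation."""
    t = as_tensor(t)
    index = np.asarray(index, dtype=np.intp)
    out = _node(t.data[index], (t,))
    out._backward = lambda g: t._accumulate(
        _scatter_add_rows(g, index, t.data.shape[0])
    )
    return out


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `t` into `num_segments` buckets given per-row ids."""
    t = as_tensor(t)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out = _node(_scatter_add_rows(t.data, segment_ids, num_segments), (t,))
    out._backward = lambda g: t._accumulate(g[segment_ids])
    return out


def _pointwise(t: Tensor, value: np.ndarray, local_grad: np.ndarray) -> Tensor:
    out = _node(value, (t,))
    out._backward = lambda g: t._accumulate(g * local_grad)
    return out


def leaky_relu(t: Tensor, negative_slope: float = 0.01) -> Tensor:
    t = as_tensor(t)
    mask = np.where(t.data > 0, 1.0, negative_slope)
    return _pointwise(t, t.data * mask, mask)


def relu(t: Tensor) -> Tensor:
    return leaky_relu(t, 0.0)


def sigmoid(t: Tensor) -> Tensor:
    t = as_tensor(t)
    # numerically stable two-sided form
    x = t.data
    s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))), np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    return _pointwise(t, s, s * (1.0 - s))


def tanh(t: Tensor) -> Tensor:
    t = as_tensor(t)
    v = np.tanh(t.data)
    return _pointwise(t, v, 1.0 - v**2)


def identity(t: Tensor) -> Tensor:
    return as_tensor(t)


def exp(t: Tensor) -> Tensor:
    t = as_tensor(t)
    v = np.exp(t.data)
    return _pointwise(t, v, v)


def rowsum(t: Tensor) -> Tensor:
    """Sum over the feature axis, keeping a (n, 1) column."""
    t = as_tensor(t)
    out = _node(t.data.sum(axis=1, keepdims=True), (t,))
    out._backward = lambda g: t._accumulate(np.broadcast_to(g, t.data.shape).copy())
    return out


def sum_all(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out = _node(np.asarray(t.data.sum()), (t,))
    out._backward = lambda g: t._accumulate(np.broadcast_to(g, t.data.shape).copy())
    return out


ACTIVATIONS = {
    "leaky_relu": leaky_relu,
    "relu": relu,
    "sigmoid": sigmoid,
    "tanh": tanh,
    "identity": identity,
}
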
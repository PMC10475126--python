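"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical substrate of the recurrent regression model: a
tape-based scalar-output backpropagation engine supporting exactly the
operations the model needs (broadcasted arithmetic, matmul, the usual
pointwise nonlinearities, reductions, gather, slicing and concatenation).
Gradients are accumulated in float64; correctness is pinned by central
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph construction helpers -----------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, parents=parents if req else (), backward=backward if req else None)

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g, a=self, p=exponent):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ b.data.swapaxes(-1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = a.data.swapaxes(-1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return self._make(out_data, (self, other), backward)

    # -- pointwise nonlinearities ---------------------------------------------

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * (1.0 - y * y))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * y * (1.0 - y))

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return self._make(self.data * mask, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * y)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return self._make(np.log(self.data), (self,), backward)

    # -- reductions ------------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        """Maximum along ``axis``; the gradient flows to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis).squeeze(axis)

        def backward(g, a=self, ax=axis, am=idx):
            if a.requires_grad:
                grad = np.zeros_like(a.data)
                np.put_along_axis(grad, np.expand_dims(am, ax), np.expand_dims(g, ax), axis=ax)
                a._accum(grad)

        return self._make(out_data, (self,), backward)

    # -- shape ops ---------------------------------------------------------------

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g, a=self, s=old):
            if a.requires_grad:
                a._accum(g.reshape(s))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]
        # basic indexing (ints/slices) hits disjoint cells, so in-place += is
        # safe; fancy integer indexing may repeat cells and needs np.add.at
        fancy = any(isinstance(k, np.ndarray) for k in (key if isinstance(key, tuple) else (key,)))

        def backward(g, a=self, k=key, f=fancy):
            if a.requires_grad:
                if a.grad is None:
                    a.grad = np.zeros_like(a.data)
                if f:
                    np.add.at(a.grad, k, g)
                else:
                    a.grad[k] += g

        return self._make(out_data, (self,), backward)

    def take_rows(self, indices: np.ndarray) -> "Tensor":
        """Gather rows (embedding lookup); duplicates accumulate on backward."""
        return self[indices]

    # -- autodiff driver ----------------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may be shared with a sibling branch of the graph
            self.grad = np.array(g, dtype=np.float64)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self) -> None:
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
            if node._backward is not None:
                node._backward(node.grad)


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)
    req = any(t.requires_grad for t in tensors)

    def backward(g, ts=tensors, offs=offsets, ax=axis):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(out_data, requires_grad=req, parents=tuple(tensors) if req else (), backward=backward if req else None)


def softmax_masked(scores: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over ``axis`` restricted to positions where ``mask`` is True.

    Masked positions receive exactly zero probability. The shift by the
    detached running maximum only stabilises the exponentials; it does not
    alter gradients.
    """
    shifted = scores + np.where(mask, 0.0, -1e30)
    shifted = shifted - np.max(shifted.data, axis=axis, keepdims=True)
    e = shifted.exp() * mask.astype(float)
    return e / e.sum(axis=axis, keepdims=True)
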
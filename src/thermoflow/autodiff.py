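"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set needed by the encoder/decoder networks and
the coupling-flow likelihood: elementwise arithmetic, matmul, tanh/exp/log,
reductions, column gather/concat, a fused softmax cross-entropy and a fused
Euclidean norm.  Gradients are accumulated by topological-order backward
passes; correctness is pinned against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "linear", "softmax_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
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

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = None

    # -- helpers ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _wrap(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req, parents=tuple(p for p in parents if p.requires_grad))
        if req:
            out._backward = backward
        return out

    def _acc(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += _unbroadcast(g, self.data.shape)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = self._make(self.data + other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._acc(g)
            if other.requires_grad:
                other._acc(g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)
        out._backward = lambda g: self._acc(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._acc(g * other.data)
            if other.requires_grad:
                other._acc(g * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = self._make(self.data / other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._acc(g / other.data)
            if other.requires_grad:
                other._acc(-g * self.data / other.data**2)

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __matmul__(self, other):
        other = self._wrap(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._acc(g @ other.data.T)
            if other.requires_grad:
                other._acc(self.data.T @ g)

        out._backward = backward
        return out

    # -- elementwise nonlinearities -------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = self._make(y, (self,), None)
        out._backward = lambda g: self._acc(g * (1.0 - y**2))
        return out

    def relu(self):
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)
        out._backward = lambda g: self._acc(g * mask)
        return out

    def exp(self):
        y = np.exp(self.data)
        out = self._make(y, (self,), None)
        out._backward = lambda g: self._acc(g * y)
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)
        out._backward = lambda g: self._acc(g / self.data)
        return out

    def square(self):
        out = self._make(self.data**2, (self,), None)
        out._backward = lambda g: self._acc(2.0 * g * self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = self._make(y, (self,), None)
        out._backward = lambda g: self._acc(0.5 * g / y)
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def logsumexp(self, axis=1):
        m = self.data.max(axis=axis, keepdims=True)
        s = np.exp(self.data - m).sum(axis=axis, keepdims=True)
        val = (m + np.log(s)).squeeze(axis)
        softmax = np.exp(self.data - m) / s
        out = self._make(val, (self,), None)
        out._backward = lambda g: self._acc(np.expand_dims(g, axis) * softmax)
        return out

    # -- shape ops -------------------------------------------------------
    def cols(self, idx):
        """Gather columns by integer index list (2-D tensors)."""
        idx = np.asarray(idx, dtype=int)
        out = self._make(self.data[:, idx], (self,), None)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, (slice(None), idx), g)
            self._acc(full)

        out._backward = backward
        return out

    def slice_cols(self, start, stop):
        """Contiguous column slice (cheaper than cols for ranges)."""
        out = self._make(self.data[:, start:stop], (self,), None)

        def backward(g):
            full = np.zeros_like(self.data)
            full[:, start:stop] = g
            self._acc(full)

        out._backward = backward
        return out

    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,), None)
        out._backward = lambda g: self._acc(g.reshape(self.data.shape))
        return out

    def norm2(self, axis=1, eps=1e-12):
        """Euclidean norm along `axis`; smoothed at the origin by `eps`."""
        y = np.sqrt((self.data**2).sum(axis=axis) + eps)
        out = self._make(y, (self,), None)
        out._backward = lambda g: self._acc(
            np.expand_dims(g / y, axis) * self.data
        )
        return out

    # -- autodiff driver -------------------------------------------------
    def backward(self, grad=None):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=float)}
        # propagate via each node's closure; closures accumulate directly into
        # parent .grad for leaves and into intermediate buffers otherwise
        for t in topo:
            t.grad = None
        self.grad = grads[id(self)]
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def linear(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Fused affine map x @ W + b."""
    out_data = x.data @ W.data + b.data
    parents = tuple(t for t in (x, W, b) if t.requires_grad)
    out = Tensor(out_data, requires_grad=bool(parents), parents=parents)
    if parents:

        def backward(g):
            if x.requires_grad:
                x._acc(g @ W.data.T)
            if W.requires_grad:
                W._acc(x.data.T @ g)
            if b.requires_grad:
                b._acc(g.sum(axis=0))

        out._backward = backward
    return out


def concat(tensors, axis=1):
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(out_data, requires_grad=req,
                 parents=tuple(t for t in tensors if t.requires_grad))
    if req:
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._acc(g[tuple(sl)])

        out._backward = backward
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Per-sample cross-entropy  -log softmax(logits)[label]  (shape (n,))."""
    labels = np.asarray(labels, dtype=int)
    x = logits.data
    m = x.max(axis=1, keepdims=True)
    e = np.exp(x - m)
    p = e / e.sum(axis=1, keepdims=True)
    n = x.shape[0]
    ce = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None))
    out = Tensor(ce, requires_grad=logits.requires_grad, parents=(logits,) if logits.requires_grad else ())
    if logits.requires_grad:

        def backward(g):
            grad = p.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._acc(grad * g[:, None])

        out._backward = backward
    return out
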
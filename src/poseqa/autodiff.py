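"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the pose-scoring network and its losses
need: broadcasting arithmetic, matmul, row gather / segment-sum (for
message passing on graphs), the usual pointwise nonlinearities, reductions,
concatenation and a numerically stable log-softmax.  Gradients are
accumulated by a topologically ordered backward sweep.

All values are float64 ndarrays.  The engine is deliberately small; it is
not a general tensor library.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "astensor", "concat", "Adam"]


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
    return grad


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("value", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, value, parents=(), backward=None, requires_grad=False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # ---- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def item(self) -> float:
        return float(self.value)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs must not hit the recursion limit
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
        for node in topo:
            node.grad = np.zeros_like(node.value)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.value.shape)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ---- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out = Tensor(self.value + other.value, (self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.value.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.value.shape)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += -g

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        out = Tensor(self.value * other.value, (self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.value, self.value.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.value, other.value.shape)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        out = Tensor(self.value / other.value, (self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.value, self.value.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(-g * self.value / other.value**2, other.value.shape)

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.value**p, (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * p * self.value ** (p - 1)

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = astensor(other)
        a, b = self.value, other.value
        out = Tensor(a @ b, (self, other))

        def bw(g):
            if self.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    self.grad += g * b
                elif b.ndim == 1:          # (n,k) @ (k,) -> (n,)
                    self.grad += np.outer(g, b)
                else:                      # (...,k) @ (k,m)
                    self.grad += g @ b.T
            if other.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    other.grad += g * a
                elif a.ndim == 1:          # (k,) @ (k,m) -> (m,)
                    other.grad += np.outer(a, g)
                else:
                    other.grad += a.T @ g

        out._backward = bw
        return out

    # ---- nonlinearities -------------------------------------------------
    def exp(self):
        v = np.exp(self.value)
        out = Tensor(v, (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * v

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.value), (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g / self.value

        out._backward = bw
        return out

    def sqrt(self):
        return self**0.5

    def tanh(self):
        v = np.tanh(self.value)
        out = Tensor(v, (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * (1.0 - v**2)

        out._backward = bw
        return out

    def sigmoid(self):
        from scipy.special import expit
        v = expit(self.value)
        out = Tensor(v, (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * v * (1.0 - v)

        out._backward = bw
        return out

    def silu(self):
        from scipy.special import expit
        s = expit(self.value)
        out = Tensor(self.value * s, (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * (s * (1.0 + self.value * (1.0 - s)))

        out._backward = bw
        return out

    # ---- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, self.value.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.value.shape)

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        out = Tensor(self.value.reshape(*shape), (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g.reshape(self.value.shape)

        out._backward = bw
        return out

    def gather(self, idx):
        """Select rows by integer index array (with repetition)."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.value[idx], (self,))

        def bw(g):
            if self.requires_grad:
                np.add.at(self.grad, idx, g)

        out._backward = bw
        return out

    def segment_sum(self, idx, n_segments: int):
        """Sum rows into ``n_segments`` bins given per-row segment ids."""
        idx = np.asarray(idx, dtype=np.intp)
        shape = (n_segments,) + self.value.shape[1:]
        acc = np.zeros(shape)
        np.add.at(acc, idx, self.value)
        out = Tensor(acc, (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g[idx]

        out._backward = bw
        return out

    def log_softmax(self, axis=-1):
        m = self.value.max(axis=axis, keepdims=True)
        z = self.value - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        logp = z - lse
        out = Tensor(logp, (self,))

        def bw(g):
            if self.requires_grad:
                p = np.exp(logp)
                self.grad += g - p * g.sum(axis=axis, keepdims=True)

        out._backward = bw
        return out

    def softmax(self, axis=-1):
        return self.log_softmax(axis=axis).exp()

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t.grad += g[tuple(sl)]

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a flat list of parameter Tensors."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
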
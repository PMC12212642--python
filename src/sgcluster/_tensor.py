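"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The interactive clustering network is full-batch and built from a small,
fixed set of dense operations (matrix products, elementwise nonlinearities,
reductions, one masked row-softmax for graph attention), so a compact
tape-based engine is sufficient.  Every operation records a backward closure;
:meth:`Tensor.backward` runs the tape in reverse topological order and
accumulates gradients into ``Tensor.grad`` for tensors created with
``requires_grad=True``.

Gradients are validated against central finite differences in the test
suite, which is the contract the rest of the package relies on.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "astensor", "masked_row_softmax", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes broadcast in the forward pass so it matches ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an attached gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    # make numpy defer to the reflected operators below in mixed expressions
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._prev: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------ plumbing
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _acc(self, g) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _out(data, prev, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = prev
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = astensor(other)

        def bw(g, a=self, b=other):
            a._acc(g)
            b._acc(g)

        return Tensor._out(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, a=self):
            a._acc(-g)

        return Tensor._out(-self.data, (self,), bw)

    def __sub__(self, other):
        other = astensor(other)

        def bw(g, a=self, b=other):
            a._acc(g)
            b._acc(-g)

        return Tensor._out(self.data - other.data, (self, other), bw)

    def __rsub__(self, other):
        return astensor(other) - self

    def __mul__(self, other):
        other = astensor(other)

        def bw(g, a=self, b=other):
            a._acc(g * b.data)
            b._acc(g * a.data)

        return Tensor._out(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)

        def bw(g, a=self, b=other):
            a._acc(g / b.data)
            b._acc(-g * a.data / (b.data * b.data))

        return Tensor._out(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bw(g, a=self):
            a._acc(g * e * a.data ** (e - 1.0))

        return Tensor._out(self.data**e, (self,), bw)

    def __matmul__(self, other):
        other = astensor(other)

        def bw(g, a=self, b=other):
            a._acc(g @ b.data.T)
            b._acc(a.data.T @ g)

        return Tensor._out(self.data @ other.data, (self, other), bw)

    def __rmatmul__(self, other):
        return astensor(other) @ self

    @property
    def T(self):
        def bw(g, a=self):
            a._acc(g.T)

        return Tensor._out(self.data.T, (self,), bw)

    # ------------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g, a=self):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._acc(np.broadcast_to(gg, a.data.shape))

        return Tensor._out(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------------ elementwise
    def log(self):
        def bw(g, a=self):
            a._acc(g / a.data)

        return Tensor._out(np.log(self.data), (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g, a=self, o=out_data):
            a._acc(g * o)

        return Tensor._out(out_data, (self,), bw)

    def relu(self):
        def bw(g, a=self):
            a._acc(g * (a.data > 0))

        return Tensor._out(np.maximum(self.data, 0.0), (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        def bw(g, a=self):
            a._acc(g * np.where(a.data > 0, 1.0, slope))

        return Tensor._out(
            np.where(self.data > 0, self.data, slope * self.data), (self,), bw
        )

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def bw(g, a=self, o=out_data):
            a._acc(g * o * (1.0 - o))

        return Tensor._out(out_data, (self,), bw)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def masked_row_softmax(logits: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax restricted to ``mask`` (boolean, same shape).

    Entries outside the mask are exactly zero in the output and receive no
    gradient.  Every row must contain at least one ``True`` entry.
    """
    mask = np.asarray(mask, dtype=bool)
    z = np.where(mask, logits.data, -np.inf)
    z = z - z.max(axis=1, keepdims=True)
    p = np.exp(z, where=np.isfinite(z), out=np.zeros_like(z))
    p /= p.sum(axis=1, keepdims=True)

    def bw(g, a=logits, p=p):
        inner = (g * p).sum(axis=1, keepdims=True)
        a._acc(p * (g - inner))

    return Tensor._out(p, (logits,), bw)


class Adam:
    """Adam optimiser over a list of parameter tensors (full-batch use)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            m_hat = self._m[i] / (1 - self.b1**self.t)
            v_hat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
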
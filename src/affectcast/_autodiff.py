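"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical core behind the recurrent forecasters.  It supports
exactly the operations those models need — broadcast elementwise arithmetic,
2-D matrix products, the sigmoid/tanh/exp/relu nonlinearities, reductions,
concatenation and basic slicing — with gradients accumulated by a topological
backward sweep.  Everything is float64.

Gradient correctness is enforced by finite-difference checks in the test
suite rather than trusted by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "softmax", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self.grad = None
        self._parents = tuple(_parents)
        self._backward = None

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        """Backpropagate from this tensor (seeded with ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))
        if out.requires_grad:
            def _back(g, a=self, b=other):
                a._accumulate(g)
                b._accumulate(g)
            out._backward = _back
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))
        if out.requires_grad:
            def _back(g, a=self, b=other):
                a._accumulate(g * b.data)
                b._accumulate(g * a.data)
            out._backward = _back
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _parents=(self,))
        if out.requires_grad:
            def _back(g, a=self, p=exponent):
                a._accumulate(g * p * a.data ** (p - 1.0))
            out._backward = _back
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        out = Tensor(self.data @ other.data, _parents=(self, other))
        if out.requires_grad:
            def _back(g, a=self, b=other):
                a._accumulate(g @ b.data.T)
                b._accumulate(a.data.T @ g)
            out._backward = _back
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))
        if out.requires_grad:
            def _back(g, a=self, i=idx):
                full = np.zeros_like(a.data)
                full[i] = g
                a._accumulate(full)
            out._backward = _back
        return out

    # -- nonlinearities ---------------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        if out.requires_grad:
            def _back(g, a=self, y=out.data):
                a._accumulate(g * y)
            out._backward = _back
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _parents=(self,))
        if out.requires_grad:
            def _back(g, a=self, y=out.data):
                a._accumulate(g * (1.0 - y * y))
            out._backward = _back
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _parents=(self,))
        if out.requires_grad:
            def _back(g, a=self, y=y):
                a._accumulate(g * y * (1.0 - y))
            out._backward = _back
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        if out.requires_grad:
            def _back(g, a=self):
                a._accumulate(g * (a.data > 0.0))
            out._backward = _back
        return out

    # -- reductions and shape ops -----------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))
        if out.requires_grad:
            def _back(g, a=self, ax=axis, kd=keepdims):
                g = np.asarray(g)
                if ax is not None and not kd:
                    g = np.expand_dims(g, ax)
                a._accumulate(np.broadcast_to(g, a.data.shape))
            out._backward = _back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        if out.requires_grad:
            def _back(g, a=self):
                a._accumulate(np.asarray(g).reshape(a.data.shape))
            out._backward = _back
        return out

    @staticmethod
    def concat(tensors, axis: int = 1) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        out = Tensor(
            np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors)
        )
        if out.requires_grad:
            sizes = [t.data.shape[axis] for t in tensors]
            offsets = np.cumsum([0] + sizes)
            def _back(g, parts=tensors, off=offsets, ax=axis):
                for t, lo, hi in zip(parts, off[:-1], off[1:]):
                    sl = [slice(None)] * g.ndim
                    sl[ax] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])
            out._backward = _back
        return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable softmax along ``axis`` (max shift is detached)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-2, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
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
            self._m[i] = self.b1 * self._m[i] + (1.0 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1.0 - self.b2) * g * g
            m_hat = self._m[i] / (1.0 - self.b1 ** self.t)
            v_hat = self._v[i] / (1.0 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
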
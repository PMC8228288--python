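"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape-based engine in the style of micrograd, lifted to arrays: each
:class:`Tensor` wraps an ndarray, records its parents and a closure that
propagates the upstream gradient, and ``backward()`` walks the tape in
reverse topological order.  Only the operations the gated-attention model
needs are provided (matmul, broadcast add/mul/div, abs, tanh, elu,
leaky-relu, softplus, masked softmax, pair gathering, reductions), each
validated against central finite differences in the test suite.

Gradients accumulate with ``+=``, so shared sub-expressions are handled
correctly; broadcasting is undone by summing over broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "masked_softmax", "bce_with_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    @property
    def T(self):
        def backward(g):
            self._accum(g.T)

        return self._make(self.data.T, (self,), backward)

    # -- nonlinearities ------------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1 - out_data**2))

        return self._make(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0):
        out_data = np.where(self.data > 0, self.data, alpha * np.expm1(self.data))

        def backward(g):
            self._accum(g * np.where(self.data > 0, 1.0, out_data + alpha))

        return self._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        out_data = np.where(self.data > 0, self.data, slope * self.data)

        def backward(g):
            self._accum(g * np.where(self.data > 0, 1.0, slope))

        return self._make(out_data, (self,), backward)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            self._accum(g / (1 + np.exp(-self.data)))

        return self._make(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            self._accum(g * sign)

        return self._make(np.abs(self.data), (self,), backward)

    # -- reductions / indexing -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self):
        n = self.data.size
        return self.sum() * (1.0 / n)

    def gather_pairs(self, rows: np.ndarray, cols: np.ndarray):
        """Extract entries ``[rows[k], cols[k]]`` of a matrix as a vector."""
        out_data = self.data[rows, cols]

        def backward(g):
            gd = np.zeros_like(self.data)
            np.add.at(gd, (rows, cols), g)
            self._accum(gd)

        return self._make(out_data, (self,), backward)

    # -- autodiff driver -----------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax restricted to ``mask`` (boolean, constant).

    Entries outside the mask get probability exactly 0; each row must have
    at least one admitted entry.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any(axis=-1).all():
        raise ValueError("masked_softmax: a row has an empty neighborhood")
    shifted = np.where(mask, scores.data, -np.inf)
    shifted = shifted - shifted.max(axis=-1, keepdims=True)
    ex = np.where(mask, np.exp(shifted), 0.0)
    out_data = ex / ex.sum(axis=-1, keepdims=True)

    def backward(g):
        # d softmax: p * (g - sum(g*p))
        dot = (g * out_data).sum(axis=-1, keepdims=True)
        scores._accum(out_data * (g - dot))

    return scores._make(out_data, (scores,), backward)


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy with logits; labels in {0, 1}.

    Uses the stable form softplus(x) - y*x averaged over entries.
    """
    labels = np.asarray(labels, dtype=np.float64)
    return (logits.softplus() - Tensor(labels) * logits).mean()


class Adam:
    """Adaptive-moment gradient descent over a list of Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 0.002,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
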
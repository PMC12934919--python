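"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the graph encoder, decoders and classifier
need: broadcasting arithmetic, 2-D/batched matmul, relu/sigmoid/log/exp,
axis reductions, reshape, concatenation, gathering along an axis, and
aggregation of a node axis by a scipy sparse matrix.  Gradients accumulate
into ``Tensor.grad`` on ``backward()``; an Adam optimizer is included.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as sp

__all__ = ["Tensor", "concat", "graph_agg", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad over axes that were broadcast to reach ``grad.shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bwd(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(self.data / other.data, (self, other), bwd)

    def __pow__(self, k: float):
        def bwd(g):
            return (g * k * self.data ** (k - 1),)

        return self._make(self.data**k, (self,), bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        """Matrix product; supports (..., a, b) @ (b, c) and 2-D @ 2-D."""
        other = self._lift(other)

        def bwd(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._make(self.data @ other.data, (self, other), bwd)

    __matmul__ = matmul

    # -- nonlinearities ---------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return self._make(s, (self,), lambda g: (g * s * (1 - s),))

    def log(self) -> "Tensor":
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        return self._make(e, (self,), lambda g: (g * e,))

    def softplus(self) -> "Tensor":
        """log(1 + exp(x)), computed stably; gradient is sigmoid(x)."""
        x = self.data
        out = np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)
        s = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._make(out, (self,), lambda g: (g * s,))

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes only through the interior."""
        mask = (self.data >= lo) & (self.data <= hi)
        return self._make(np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,))

    # -- reductions / shaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape) -> "Tensor":
        old = self.shape
        return self._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def take(self, indices, axis: int) -> "Tensor":
        """Gather along an axis; backward scatter-adds."""
        idx = np.asarray(indices, dtype=int)

        def bwd(g):
            out = np.zeros(self.shape)
            np.add.at(out, (slice(None),) * axis + (idx,), g)
            return (out,)

        return self._make(np.take(self.data, idx, axis=axis), (self,), bwd)

    # -- autodiff driver ---------------------------------------------------
    def backward(self) -> None:
        """Reverse-mode pass from a scalar loss, accumulating leaf ``.grad``.

        Nodes are visited in reverse topological order; iterative traversal
        avoids recursion limits on deep graphs.
        """
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if id(node) in seen or not node.requires_grad:
                continue
            if done:
                seen.add(id(node))
                topo.append(node)
            else:
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for t in reversed(topo):
            g = grads.get(id(t))
            if g is None:
                continue
            if t._backward is None:  # leaf parameter or input
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def graph_agg(A: sp.spmatrix, t: Tensor) -> Tensor:
    """Apply a sparse (K, M) operator along the node axis of a (B, M, d) tensor.

    Forward computes ``out[b] = A @ t[b]`` for every batch slice; backward
    applies ``A.T``.  Also accepts 2-D (M, d) input.
    """
    A = A.tocsr()
    AT = A.T.tocsr()

    def apply(op, x: np.ndarray) -> np.ndarray:
        if x.ndim == 2:
            return op @ x
        b, m, d = x.shape
        y = op @ x.transpose(1, 0, 2).reshape(m, b * d)
        return y.reshape(op.shape[0], b, d).transpose(1, 0, 2)

    out = Tensor(apply(A, t.data))
    if t.requires_grad:
        out.requires_grad = True
        out._parents = (t,)
        out._backward = lambda g: (apply(AT, g),)
    return out


class Adam:
    """Adam over a dict of parameter Tensors (requires_grad=True)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-2,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
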
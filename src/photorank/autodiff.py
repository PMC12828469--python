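"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core behind the package's two trainable models (the
dual-input MLP and the scaled-down transformer encoder).  It implements a
tape-based autograd with exactly the operations those models need:
broadcasting add/mul, (batched) matmul, ReLU/GELU/tanh, softmax, layer
normalization, embedding lookup, reshape/transpose/concatenate, and a
fused weighted cross-entropy.  Gradients are checked against central
finite differences in the test suite.

Everything is float64 and single-threaded-deterministic: given the same
seed and inputs, training produces bitwise-identical results.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

_SQRT1_2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- graph bookkeeping -------------------------------------------------

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this node."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [t]
            order = []
            while stack:
                node = stack.pop()
                if id(node) in seen:
                    continue
                seen.add(id(node))
                order.append(node)
                stack.extend(node._parents)
            # order is a DFS preorder; sort topologically by repeated passes
            topo.extend(order)

        visit(self)
        # Kahn-style topological order over the collected subgraph
        indeg: dict[int, int] = {id(t): 0 for t in topo}
        by_id = {id(t): t for t in topo}
        children: dict[int, list[int]] = {id(t): [] for t in topo}
        for t in topo:
            for p in t._parents:
                indeg[id(p)] += 1
                children[id(t)].append(id(p))
        self._accumulate(grad)
        ready = [t for t in topo if indeg[id(t)] == 0]
        while ready:
            node = ready.pop()
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            for pid in children[id(node)]:
                indeg[pid] -= 1
                if indeg[pid] == 0:
                    ready.append(by_id[pid])

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _as_tensor(-1.0)))

    def __matmul__(self, other):
        return matmul(self, other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- primitives ------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product; supports stacked (batched) operands like np.matmul."""
    data = np.matmul(a.data, b.data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    data = x.data * mask

    def backward(g):
        x._accumulate(g * mask)

    return _make(data, (x,), backward)


def gelu(x: Tensor) -> Tensor:
    """Exact GELU: x * Phi(x)."""
    phi = 0.5 * (1.0 + erf(x.data * _SQRT1_2))
    data = x.data * phi

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data**2)
        x._accumulate(g * (phi + x.data * pdf))

    return _make(data, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    data = np.tanh(x.data)

    def backward(g):
        x._accumulate(g * (1.0 - data**2))

    return _make(data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        x._accumulate(data * (g - dot))

    return _make(data, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalization over the last axis with learned scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    data = xhat * gamma.data + beta.data

    def backward(g):
        n = x.data.shape[-1]
        gxhat = g * gamma.data
        dx = (
            inv
            / n
            * (
                n * gxhat
                - gxhat.sum(axis=-1, keepdims=True)
                - xhat * (gxhat * xhat).sum(axis=-1, keepdims=True)
            )
        )
        x._accumulate(dx)
        gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
        beta._accumulate(_unbroadcast(g, beta.data.shape))

    return _make(data, (x, gamma, beta), backward)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather: weight[ids]."""
    ids = np.asarray(ids)
    data = weight.data[ids]

    def backward(g):
        if weight.grad is None:
            weight.grad = np.zeros_like(weight.data)
        np.add.at(weight.grad, ids.reshape(-1), g.reshape(-1, weight.data.shape[-1]))

    return _make(data, (weight,), backward)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(x.data.shape))

    return _make(data, (x,), backward)


def transpose(x: Tensor, axes: tuple[int, ...]) -> Tensor:
    data = x.data.transpose(axes)
    inverse = np.argsort(axes)

    def backward(g):
        x._accumulate(g.transpose(inverse))

    return _make(data, (x,), backward)


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _make(data, tuple(tensors), backward)


def select_position(x: Tensor, pos: int) -> Tensor:
    """Select one position along axis 1: x[:, pos, :]."""
    data = x.data[:, pos, :]

    def backward(g):
        grad = np.zeros_like(x.data)
        grad[:, pos, :] = g
        x._accumulate(grad)

    return _make(data, (x,), backward)


def mean(x: Tensor) -> Tensor:
    data = np.asarray(x.data.mean())
    n = x.data.size

    def backward(g):
        x._accumulate(np.full_like(x.data, float(g) / n))

    return _make(data, (x,), backward)


def cross_entropy(
    logits: Tensor,
    targets: np.ndarray,
    sample_weights: np.ndarray | None = None,
    ignore_index: int = -100,
) -> Tensor:
    """Fused softmax + negative log-likelihood, averaged over kept rows.

    ``targets`` is an integer array of shape (N,); rows whose target equals
    ``ignore_index`` contribute nothing.  ``sample_weights`` rescales each
    row's loss; the average is weight-normalized, so uniform weights of any
    scale reproduce the unweighted mean.
    """
    targets = np.asarray(targets)
    keep = targets != ignore_index
    if not keep.any():
        raise ValueError("cross_entropy: no rows left after ignore_index masking")
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    idx = np.where(keep)[0]
    tgt = targets[idx]
    if sample_weights is None:
        w = np.ones(len(idx))
    else:
        w = np.asarray(sample_weights, dtype=np.float64)[idx]
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("cross_entropy: nonpositive total sample weight")
    loss = -(w * logp[idx, tgt]).sum() / wsum
    data = np.asarray(loss)

    def backward(g):
        p = np.exp(logp)
        grad = np.zeros_like(logits.data)
        grad[idx] = p[idx] * (w / wsum)[:, None]
        grad[idx, tgt] -= w / wsum
        logits._accumulate(grad * float(g))

    return _make(data, (logits,), backward)


# -- parameters and optimization -------------------------------------------


def parameter(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int | None = None) -> Tensor:
    """Uniform fan-in initialized trainable tensor."""
    if fan_in is None:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    t = Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)
    return t


def zeros_parameter(shape: tuple[int, ...]) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def ones_parameter(shape: tuple[int, ...]) -> Tensor:
    return Tensor(np.ones(shape), requires_grad=True)


class Adam:
    """Adam optimizer over a list of Tensors."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Affine map x @ w + b."""
    return add(matmul(x, w), b)
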
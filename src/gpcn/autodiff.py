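"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just the handful of operations the GCN-family models need: (batched) matrix
products, broadcast addition, elementwise ReLU/sigmoid, concatenation,
transposition, row softmax, and reductions.  Gradients for broadcast operands
are sum-reduced back to the operand's shape, so a ``(n, n)`` structure matrix
can multiply a ``(batch, n, F)`` feature tensor directly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Var", "matmul", "add", "relu", "sigmoid", "concat", "transpose",
           "row_softmax", "sum_all", "mean_square_error", "scale", "backward"]


class Var:
    """Node in the computation tape: a value, accumulated grad, and parents."""

    __slots__ = ("value", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, value, parents=(), backward_fn=None, requires_grad=True):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self.parents = parents
        self._backward = backward_fn
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.value.shape

    def accumulate(self, g):
        self.grad = g if self.grad is None else self.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def matmul(a: Var, b: Var) -> Var:
    out_val = a.value @ b.value

    def bw(out):
        g = out.grad
        if a.requires_grad:
            ga = g @ np.swapaxes(b.value, -1, -2)
            a.accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.value, -1, -2) @ g
            b.accumulate(_unbroadcast(gb, b.shape))

    return Var(out_val, (a, b), bw)


def add(a: Var, b: Var) -> Var:
    def bw(out):
        if a.requires_grad:
            a.accumulate(_unbroadcast(out.grad, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(out.grad, b.shape))

    return Var(a.value + b.value, (a, b), bw)


def scale(a: Var, c: float) -> Var:
    def bw(out):
        if a.requires_grad:
            a.accumulate(c * out.grad)

    return Var(c * a.value, (a,), bw)


def relu(a: Var) -> Var:
    mask = a.value > 0

    def bw(out):
        if a.requires_grad:
            a.accumulate(out.grad * mask)

    return Var(a.value * mask, (a,), bw)


def sigmoid(a: Var) -> Var:
    # clip to keep exp in range; the saturated limits are exact anyway
    s = 1.0 / (1.0 + np.exp(-np.clip(a.value, -500.0, 500.0)))

    def bw(out):
        if a.requires_grad:
            a.accumulate(out.grad * s * (1.0 - s))

    return Var(s, (a,), bw)


def identity(a: Var) -> Var:
    return a


def concat(parts: list[Var], axis: int = -1) -> Var:
    sizes = [p.value.shape[axis] for p in parts]

    def bw(out):
        offs = np.cumsum([0] + sizes)
        for p, lo, hi in zip(parts, offs[:-1], offs[1:]):
            if p.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                p.accumulate(out.grad[tuple(sl)])

    return Var(np.concatenate([p.value for p in parts], axis=axis), tuple(parts), bw)


def transpose(a: Var) -> Var:
    def bw(out):
        if a.requires_grad:
            a.accumulate(np.swapaxes(out.grad, -1, -2))

    return Var(np.swapaxes(a.value, -1, -2), (a,), bw)


def row_softmax(a: Var) -> Var:
    z = a.value - a.value.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)

    def bw(out):
        if a.requires_grad:
            g = out.grad
            a.accumulate(s * (g - (g * s).sum(axis=-1, keepdims=True)))

    return Var(s, (a,), bw)


def sum_all(a: Var) -> Var:
    def bw(out):
        if a.requires_grad:
            a.accumulate(np.full(a.shape, out.grad))

    return Var(a.value.sum(), (a,), bw)


def mean_square_error(pred: Var, target: np.ndarray) -> Var:
    diff = pred.value - target
    n = diff.size

    def bw(out):
        if pred.requires_grad:
            pred.accumulate(out.grad * 2.0 * diff / n)

    return Var(np.mean(diff**2), (pred,), bw)


def backward(root: Var) -> None:
    """Reverse-topological gradient sweep seeding ``d root / d root = 1``."""
    order: list[Var] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    root.grad = np.ones_like(root.value)
    for node in reversed(order):
        if node._backward is not None:
            node._backward(node)
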
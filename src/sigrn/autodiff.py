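"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations the SEM-VAE needs are implemented: broadcasting
arithmetic, matmul, tanh, softplus, exp, log, abs, reductions, and the
right-sided linear solve ``Y = Z @ inv(B)`` with its adjoint.  Gradients are
accumulated by a topologically ordered sweep over the recorded tape.  The
implementation is checked against central finite differences in the test
suite.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Var:
    """A node in the computation graph holding a value and, later, a gradient."""

    __slots__ = ("value", "grad", "parents", "backward_fn")

    def __init__(
        self,
        value: np.ndarray | float,
        parents: tuple["Var", ...] = (),
        backward_fn: Callable[[np.ndarray], tuple[np.ndarray, ...]] | None = None,
    ):
        self.value = np.asarray(value, dtype=float)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self.backward_fn = backward_fn

    @property
    def shape(self):
        return self.value.shape

    # --- graph-building operators -------------------------------------
    def __add__(self, other):
        other = as_var(other)
        return Var(
            self.value + other.value,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __sub__(self, other):
        other = as_var(other)
        return Var(
            self.value - other.value,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)),
        )

    def __rsub__(self, other):
        return as_var(other).__sub__(self)

    def __mul__(self, other):
        other = as_var(other)
        return Var(
            self.value * other.value,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.value, self.shape),
                _unbroadcast(g * self.value, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __neg__(self):
        return Var(-self.value, (self,), lambda g: (-g,))

    def __matmul__(self, other):
        other = as_var(other)
        return Var(
            self.value @ other.value,
            (self, other),
            lambda g: (g @ other.value.T, self.value.T @ g),
        )

    def detach(self) -> "Var":
        """A new leaf with the same value and no history (stop-gradient)."""
        return Var(self.value.copy())


def as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(x)


def tanh(x: Var) -> Var:
    t = np.tanh(x.value)
    return Var(t, (x,), lambda g: (g * (1.0 - t * t),))


def softplus(x: Var) -> Var:
    # numerically stable: log(1 + e^x) = max(x,0) + log1p(e^{-|x|})
    v = np.maximum(x.value, 0.0) + np.log1p(np.exp(-np.abs(x.value)))
    sig = 1.0 / (1.0 + np.exp(-x.value))
    return Var(v, (x,), lambda g: (g * sig,))


def exp(x: Var) -> Var:
    e = np.exp(x.value)
    return Var(e, (x,), lambda g: (g * e,))


def log(x: Var) -> Var:
    return Var(np.log(x.value), (x,), lambda g: (g / x.value,))


def square(x: Var) -> Var:
    return Var(x.value**2, (x,), lambda g: (2.0 * g * x.value,))


def absval(x: Var) -> Var:
    # subgradient 0 at 0
    return Var(np.abs(x.value), (x,), lambda g: (g * np.sign(x.value),))


def mean(x: Var) -> Var:
    n = x.value.size
    return Var(x.value.mean(), (x,), lambda g: (np.full(x.shape, float(g) / n),))


def vsum(x: Var) -> Var:
    return Var(x.value.sum(), (x,), lambda g: (np.full(x.shape, float(g)),))


def tanh_outer(x: Var, w: Var, b: Var) -> Var:
    """Fused per-gene hidden layer: tanh(x[..., None] * w + b) -> (B, G, H).

    One node for the whole layer keeps the number of (B, G, H) temporaries
    low; the cached tanh output is reused in the backward pass.
    """
    t = np.tanh(x.value[..., None] * w.value + b.value)
    n_hidden = w.value.shape[0]

    def backward(g: np.ndarray):
        du = t * t
        np.subtract(1.0, du, out=du)
        du *= g
        flat = du.reshape(-1, n_hidden)
        return du @ w.value, flat.T @ x.value.ravel(), flat.sum(axis=0)

    return Var(t, (x, w, b), backward)


def head_sum(t: Var, w: Var, b: Var) -> Var:
    """Fused output head: t @ w + b with t of shape (B, G, H), w (H,), b (1,)."""
    val = t.value @ w.value + b.value
    n_hidden = w.value.shape[0]

    def backward(g: np.ndarray):
        return (
            g[..., None] * w.value,
            t.value.reshape(-1, n_hidden).T @ g.ravel(),
            np.array([g.sum()]),
        )

    return Var(val, (t, w, b), backward)


def zero_grads(root: Var) -> None:
    """Clear ``.grad`` on every node reachable from ``root``."""
    stack = [root]
    seen: set[int] = set()
    while stack:
        node = stack.pop()
        if id(node) in seen:
            continue
        seen.add(id(node))
        node.grad = None
        stack.extend(node.parents)


def unsqueeze_last(x: Var) -> Var:
    """Append a trailing axis of size 1 (for per-gene scalar-MLP broadcasting)."""
    return Var(x.value[..., None], (x,), lambda g: (g.reshape(x.value.shape),))


def sum_last(x: Var) -> Var:
    """Sum over the trailing axis."""
    n = x.value.shape[-1]
    return Var(
        x.value.sum(axis=-1),
        (x,),
        lambda g: (np.broadcast_to(g[..., None], g.shape + (n,)).copy(),),
    )


def transpose(x: Var) -> Var:
    return Var(x.value.T, (x,), lambda g: (g.T,))


def mul_mask(x: Var, mask: np.ndarray) -> Var:
    """Multiply by a constant matrix (e.g. a dropout mask or diagonal mask)."""
    return Var(x.value * mask, (x,), lambda g: (g * mask,))


def solve_right(z: Var, b: Var) -> Var:
    """Y = Z @ inv(B), computed by a linear solve, with adjoints for Z and B.

    From Y B = Z:  dL/dZ = G @ inv(B)^T,  dL/dB = -Y^T @ (G @ inv(B)^T).
    """
    b_val = b.value
    y = np.linalg.solve(b_val.T, z.value.T).T

    def backward(g: np.ndarray):
        gb_inv_t = np.linalg.solve(b_val, g.T).T  # G @ inv(B)^T
        return gb_inv_t, -(y.T @ gb_inv_t)

    return Var(y, (z, b), backward)


def backward(root: Var) -> None:
    """Populate ``.grad`` on every node reachable from ``root`` (a scalar)."""
    if root.value.size != 1:
        raise ValueError("backward() expects a scalar loss")
    order: list[Var] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    root.grad = np.ones_like(root.value)
    for node in reversed(order):
        if node.backward_fn is None or node.grad is None:
            continue
        grads = node.backward_fn(node.grad)
        for parent, g in zip(node.parents, grads):
            if parent.grad is None:
                parent.grad = np.array(g, dtype=float, copy=True)
            else:
                parent.grad = parent.grad + g
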
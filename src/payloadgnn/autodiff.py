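"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The graph layers in :mod:`payloadgnn.model` need only a small set of
primitives (dense affine maps, gather/scatter along the edge list,
element-wise nonlinearities and a numerically stable binary cross-entropy).
This module provides exactly those, with float64 arithmetic throughout so
layer outputs can be compared against brute-force oracles at tight
tolerances.

Gradients are accumulated by topological traversal of the operation graph;
every primitive registers a vector-Jacobian product closure at build time.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "leaky_relu",
    "relu",
    "sigmoid",
    "exp",
    "log",
    "segment_sum",
    "bce_with_logits",
    "grad_check",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence[tuple["Tensor", Callable[[np.ndarray], np.ndarray]]] = (),
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = tuple(p for p in _parents if p[0].requires_grad)
        self.requires_grad = requires_grad or bool(self._parents)

    # ------------------------------------------------------------------ util
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; molecule batches can nest deeply
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, vjp in node._parents:
                pg = vjp(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data + other.data
        return Tensor(
            out_data,
            _parents=(
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ),
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor(-self.data, _parents=((self, lambda g: -g),))

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            _parents=(
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor(
            self.data / other.data,
            _parents=(
                (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.data / (other.data**2), other.data.shape
                    ),
                ),
            ),
        )

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        a, b = self.data, other.data
        return Tensor(
            a @ b,
            _parents=(
                (self, lambda g: _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)),
                (other, lambda g: _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)),
            ),
        )

    def __getitem__(self, idx) -> "Tensor":
        """Gather; `idx` is an integer array (row gather) or basic slice."""

        def vjp(g: np.ndarray) -> np.ndarray:
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return out

        return Tensor(self.data[idx], _parents=((self, vjp),))

    # ---------------------------------------------------------------- shape
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor(
            self.data.reshape(shape), _parents=((self, lambda g: g.reshape(old)),)
        )

    def transpose(self, *axes) -> "Tensor":
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes), _parents=((self, lambda g: g.transpose(inv)),)
        )

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g: np.ndarray) -> np.ndarray:
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            g_exp = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(g_exp, self.data.shape).copy()

        return Tensor(out, _parents=((self, vjp),))

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


# ------------------------------------------------------------------ pointwise
def relu(t: Tensor) -> Tensor:
    mask = t.data > 0
    return Tensor(np.where(mask, t.data, 0.0), _parents=((t, lambda g: g * mask),))


def leaky_relu(t: Tensor, slope: float = 0.2) -> Tensor:
    mask = t.data > 0
    scale = np.where(mask, 1.0, slope)
    return Tensor(t.data * scale, _parents=((t, lambda g: g * scale),))


def sigmoid(t: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(t.data, -500, 500)))
    return Tensor(s, _parents=((t, lambda g: g * s * (1.0 - s)),))


def exp(t: Tensor) -> Tensor:
    e = np.exp(t.data)
    return Tensor(e, _parents=((t, lambda g: g * e),))


def log(t: Tensor) -> Tensor:
    return Tensor(np.log(t.data), _parents=((t, lambda g: g / t.data),))


def tanh(t: Tensor) -> Tensor:
    h = np.tanh(t.data)
    return Tensor(h, _parents=((t, lambda g: g * (1.0 - h * h)),))


# ----------------------------------------------------------------- structural
def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out = np.concatenate([t.data for t in tensors], axis=axis)

    parents = []
    for k, t in enumerate(tensors):
        lo, hi = offsets[k], offsets[k + 1]

        def vjp(g: np.ndarray, lo=lo, hi=hi) -> np.ndarray:
            slicer = [slice(None)] * g.ndim
            slicer[axis] = slice(lo, hi)
            return g[tuple(slicer)]

        parents.append((t, vjp))
    return Tensor(out, _parents=parents)


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `t` into `num_segments` buckets given by `segment_ids`."""
    segment_ids = np.asarray(segment_ids)
    out = np.zeros((num_segments,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(out, segment_ids, t.data)
    return Tensor(out, _parents=((t, lambda g: g[segment_ids]),))


def bce_with_logits(logits: Tensor, targets: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    """Mean binary cross-entropy over unmasked entries, stable in the logits.

    loss_i = max(z,0) - z*y + log(1 + exp(-|z|)); masked entries contribute
    exactly zero to both value and gradient.
    """
    z = logits.data
    y = np.asarray(targets, dtype=np.float64)
    if mask is None:
        mask = np.ones_like(y)
    mask = np.asarray(mask, dtype=np.float64)
    n_obs = mask.sum()
    if n_obs == 0:
        raise ValueError("bce_with_logits: every label is masked")
    per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    value = (per * mask).sum() / n_obs

    def vjp(g: np.ndarray) -> np.ndarray:
        s = 1.0 / (1.0 + np.exp(-z))
        return g * mask * (s - y) / n_obs

    return Tensor(value, _parents=((logits, vjp),))


# ------------------------------------------------------------------- testing
def grad_check(
    fn: Callable[[Tensor], Tensor],
    x: np.ndarray,
    eps: float = 1e-6,
    atol: float = 1e-5,
) -> float:
    """Max abs difference between backprop and central finite differences."""
    xt = Tensor(x, requires_grad=True)
    out = fn(xt)
    out.backward()
    analytic = xt.grad.copy()
    numeric = np.zeros_like(analytic)
    flat = x.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(Tensor(x)).data.item()
        flat[i] = orig - eps
        lo = fn(Tensor(x)).data.item()
        flat[i] = orig
        numeric.reshape(-1)[i] = (hi - lo) / (2 * eps)
    err = float(np.max(np.abs(analytic - numeric)))
    if err > atol:
        raise AssertionError(f"gradient check failed: max abs err {err:.3g}")
    return err
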
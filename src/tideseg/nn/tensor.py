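"""Reverse-mode automatic differentiation over NumPy arrays.

A small tape-based engine: each :class:`Tensor` wraps an ``ndarray`` and
remembers the tensors it was computed from together with a closure that
propagates the adjoint. ``Tensor.backward()`` runs the closures in reverse
topological order. Only the primitives the segmentation network needs are
implemented (broadcast arithmetic, matmul, reductions, shape ops, activations,
2-D/1-D convolution, bilinear resize and the two classification losses); the
transformer blocks and heads are compositions of these.

Gradient correctness of every primitive is checked against central finite
differences in the test-suite.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import special as _sp_special

__all__ = ["Tensor", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64 if not isinstance(data, np.ndarray) else data.dtype)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)
        # topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out_data = a.data + b.data

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(out_data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out_data = a.data * b.data

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def backward(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._make(out_data, (a,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out_data = a.data @ b.data

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(out_data, (a, b), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not a.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).astype(a.dtype))

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --------------------------------------------------------------- shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        out_data = a.data.reshape(shape)

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(a.shape))

        return Tensor._make(out_data, (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        out_data = a.data.transpose(axes)

        def backward(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._make(out_data, (a,), backward)

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor._make(out_data, (a,), backward)

    def pad2d(self, pad_h: int, pad_w: int):
        """Zero-pad the trailing two axes symmetrically."""
        a = self
        width = [(0, 0)] * (a.ndim - 2) + [(pad_h, pad_h), (pad_w, pad_w)]
        out_data = np.pad(a.data, width)

        def backward(g):
            if a.requires_grad:
                sl = [slice(None)] * (a.ndim - 2)
                sl += [slice(pad_h, g.shape[-2] - pad_h), slice(pad_w, g.shape[-1] - pad_w)]
                a._accum(g[tuple(sl)])

        return Tensor._make(out_data, (a,), backward)

    # -------------------------------------------------------------- activations
    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        s = _sp_special.expit(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return Tensor._make(s, (a,), backward)

    def gelu(self):
        """Exact Gaussian-error-linear unit, x * Phi(x)."""
        a = self
        x = a.data
        phi = 0.5 * (1.0 + _sp_special.erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)

        def backward(g):
            if a.requires_grad:
                a._accum(g * (phi + x * pdf))

        return Tensor._make(x * phi, (a,), backward)

    def exp(self):
        a = self
        e = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * e)

        return Tensor._make(e, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def softmax(self, axis: int = -1):
        a = self
        m = a.data.max(axis=axis, keepdims=True)
        e = np.exp(a.data - m)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if a.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                a._accum(s * (g - dot))

        return Tensor._make(s, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, ts, backward)
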
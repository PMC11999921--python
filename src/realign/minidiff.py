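"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the primitives the recurrent backbone and the
alignment loss need: broadcasting arithmetic, matrix multiplication, 2-D
convolution and pooling, ReLU, reductions, reshaping/concatenation, a fused
softmax cross-entropy, and an Adam optimizer.  All computation is float64 on
CPU; graphs are built eagerly and freed after :meth:`Tensor.backward`.

Gradient correctness is established by central-difference checks in the test
suite rather than assumed.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concat",
    "no_grad",
    "is_grad_enabled",
    "Adam",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of numpy broadcasting)."""
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
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of a scalar (or supplied cotangent) output."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._backward = None
                node._parents = ()

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            a._accum(_unbroadcast(g / b.data, a.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return self._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        a = self

        def backward(g):
            a._accum(g * exponent * a.data ** (exponent - 1))

        return self._make(a.data ** exponent, (a,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other
        if a.ndim != 2 or b.ndim != 2:
            raise ValueError("matmul supports 2-D tensors only")

        def backward(g):
            a._accum(g @ b.data.T)
            b._accum(a.data.T @ g)

        return self._make(a.data @ b.data, (a, b), backward)

    # -------------------------------------------------------------- unary ops
    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accum(g * mask)

        return self._make(np.where(mask, a.data, 0.0), (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accum(g / a.data)

        return self._make(np.log(a.data), (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accum(g * out_data)

        return self._make(out_data, (a,), backward)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            a._accum(g * 0.5 / out_data)

        return self._make(out_data, (a,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            g_exp = g if keepdims else np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g_exp, a.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ shape moves
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old_shape = a.shape

        def backward(g):
            a._accum(g.reshape(old_shape))

        return self._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, axes: Sequence[int]):
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(inv))

        return self._make(a.data.transpose(axes), (a,), backward)

    @property
    def T(self):
        return self.transpose((1, 0))

    # --------------------------------------------------------- neural-net ops
    def conv2d(self, weight: "Tensor", bias: "Tensor", stride: int = 1,
               padding: int = 0) -> "Tensor":
        """2-D convolution, NCHW layout, square kernels, via im2col."""
        x, w, b = self, weight, bias
        n, c, h, wd = x.shape
        oc, ic, kh, kw = w.shape
        if ic != c:
            raise ValueError(f"channel mismatch: input {c}, kernel {ic}")
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        ho = (h + 2 * padding - kh) // stride + 1
        wo = (wd + 2 * padding - kw) // stride + 1
        if ho < 1 or wo < 1:
            raise ValueError("input spatially smaller than kernel")
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
        # (n, c, ho, wo, kh, kw) -> (n*ho*wo, c*kh*kw)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
        wmat = w.data.reshape(oc, c * kh * kw)
        out = cols @ wmat.T + b.data
        out = out.reshape(n, ho, wo, oc).transpose(0, 3, 1, 2)

        def backward(g):
            g_cols = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, oc)
            if b.requires_grad:
                b._accum(g_cols.sum(axis=0))
            if w.requires_grad:
                w._accum((g_cols.T @ cols).reshape(w.shape))
            if x.requires_grad:
                d_cols = (g_cols @ wmat).reshape(n, ho, wo, c, kh, kw)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += \
                            d_cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                x._accum(dxp)

        return self._make(out, (x, w, b), backward)

    def maxpool2d(self, kernel: int = 3, stride: int = 2, padding: int = 1) -> "Tensor":
        x = self
        n, c, h, w = x.shape
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
        ho = (h + 2 * padding - kernel) // stride + 1
        wo = (w + 2 * padding - kernel) // stride + 1
        win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
        flat = win.reshape(n, c, ho, wo, kernel * kernel)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            dxp = np.zeros_like(xp)
            ni, ci, hi, wi = np.indices((n, c, ho, wo))
            rows = hi * stride + idx // kernel
            cols = wi * stride + idx % kernel
            np.add.at(dxp, (ni, ci, rows, cols), g)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

        return self._make(out, (x,), backward)

    def avg_pool_to(self, grid: int) -> "Tensor":
        """Adaptive average pooling of an NCHW tensor to ``grid x grid``."""
        x = self
        n, c, h, w = x.shape
        hb = np.linspace(0, h, grid + 1).astype(int)
        wb = np.linspace(0, w, grid + 1).astype(int)
        out = np.empty((n, c, grid, grid))
        for i in range(grid):
            for j in range(grid):
                out[:, :, i, j] = x.data[:, :, hb[i]:hb[i + 1], wb[j]:wb[j + 1]].mean(axis=(2, 3))

        def backward(g):
            dx = np.zeros_like(x.data)
            for i in range(grid):
                for j in range(grid):
                    area = (hb[i + 1] - hb[i]) * (wb[j + 1] - wb[j])
                    dx[:, :, hb[i]:hb[i + 1], wb[j]:wb[j + 1]] += \
                        g[:, :, i, j][:, :, None, None] / area
            x._accum(dx)

        return self._make(out, (x,), backward)

    def log_softmax(self) -> "Tensor":
        """Row-wise log-softmax of a 2-D tensor, numerically stabilised."""
        x = self
        shifted = x.data - x.data.max(axis=1, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        out = shifted - lse
        probs = np.exp(out)

        def backward(g):
            x._accum(g - probs * g.sum(axis=1, keepdims=True))

        return self._make(out, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(data)
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                t._accum(piece)

        out._backward = backward
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under row-wise softmax."""
    labels = np.asarray(labels)
    n = logits.shape[0]
    logp = logits.log_softmax()
    picked = logp.data[np.arange(n), labels]
    x = logp

    out = Tensor(-picked.mean())
    if _GRAD_ENABLED and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def backward(g):
            grad = np.zeros_like(x.data)
            grad[np.arange(n), labels] = -g / n
            x._accum(grad)

        out._backward = backward
    return out


class Adam:
    """Adam optimizer with the standard bias correction."""

    def __init__(self, params: Iterable[Tensor], lr: float = 2e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
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
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
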
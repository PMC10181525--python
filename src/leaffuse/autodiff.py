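"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

This is the numerical core behind the deep backbone and the classification
heads: a :class:`Tensor` wrapping a float64 ndarray, a small set of primitive
operations (elementwise arithmetic, matmul, reshape/transpose, reductions,
softmax, convolutions, pooling) each carrying a hand-written backward rule,
and topological-sort backpropagation.  Everything is deterministic: no
threading, no fused kernels, plain IEEE float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = ["Tensor", "cross_entropy", "softmax", "log_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd engine ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep graphs (27-block stages) overflow recursion
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

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._from_op(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)

        return Tensor._from_op(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._from_op(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._from_op(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        a = self

        def backward(g):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._from_op(a.data ** p, (a,), backward)

    def sqrt(self):
        a = self
        out = np.sqrt(a.data)

        def backward(g):
            a._accum(g * 0.5 / np.maximum(out, 1e-300))

        return Tensor._from_op(out, (a,), backward)

    def exp(self):
        a = self
        out = np.exp(a.data)

        def backward(g):
            a._accum(g * out)

        return Tensor._from_op(out, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accum(g / a.data)

        return Tensor._from_op(np.log(a.data), (a,), backward)

    # -- activations ----------------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accum(g * mask)

        return Tensor._from_op(a.data * mask, (a,), backward)

    def gelu(self):
        """Exact Gaussian-error-linear unit: x * Phi(x)."""
        a = self
        x = a.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)

        def backward(g):
            a._accum(g * (phi + x * pdf))

        return Tensor._from_op(x * phi, (a,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def backward(g):
            a._accum(g.reshape(old))

        return Tensor._from_op(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        axes = axes or tuple(reversed(range(a.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(inv))

        return Tensor._from_op(a.data.transpose(axes), (a,), backward)

    def pad_last(self, n: int):
        """Zero-pad the last axis by ``n`` trailing entries."""
        if n < 0:
            raise ValueError("pad length must be >= 0")
        if n == 0:
            return self
        a = self
        width = [(0, 0)] * (a.data.ndim - 1) + [(0, n)]

        def backward(g):
            a._accum(g[..., : a.data.shape[-1]])

        return Tensor._from_op(np.pad(a.data, width), (a,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        shape = a.data.shape

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, shape).copy())

        return Tensor._from_op(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- matmul ---------------------------------------------------------------
    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._from_op(a.data @ b.data, (a, b), backward)

    # -- convolution / pooling ------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0, groups: int = 1):
        """2-D cross-correlation, NCHW layout, square stride/padding.

        weight: (O, C // groups, kh, kw); depthwise convolution is
        ``groups == C`` with weight (C, 1, kh, kw).
        """
        a, w = self, weight
        N, C, H, W = a.data.shape
        O, Cg, kh, kw = w.data.shape
        if C % groups or O % groups or Cg != C // groups:
            raise ValueError("channel counts incompatible with groups")
        xp = np.pad(a.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
        Ho, Wo = win.shape[2], win.shape[3]
        wing = win.reshape(N, groups, Cg, Ho, Wo, kh, kw)
        wg = w.data.reshape(groups, O // groups, Cg, kh, kw)
        out = np.einsum("ngchwyx,gocyx->ngohw", wing, wg, optimize=True)
        out = out.reshape(N, O, Ho, Wo)
        if bias is not None:
            out = out + bias.data.reshape(1, O, 1, 1)
        parents = (a, w) if bias is None else (a, w, bias)

        def backward(g):
            gg = g.reshape(N, groups, O // groups, Ho, Wo)
            if w.requires_grad:
                gw = np.einsum("ngohw,ngchwyx->gocyx", gg, wing, optimize=True)
                w._accum(gw.reshape(O, Cg, kh, kw))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if a.requires_grad:
                gwin = np.einsum("ngohw,gocyx->ngchwyx", gg, wg, optimize=True)
                gwin = gwin.reshape(N, C, Ho, Wo, kh, kw)
                gxp = np.zeros_like(xp)
                for y in range(kh):
                    for x in range(kw):
                        gxp[:, :, y:y + Ho * stride:stride,
                            x:x + Wo * stride:stride] += gwin[:, :, :, :, y, x]
                if padding:
                    gxp = gxp[:, :, padding:padding + H, padding:padding + W]
                a._accum(gxp)

        return Tensor._from_op(out, parents, backward)

    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """1-D cross-correlation, NCL layout; weight (O, C, k)."""
        a, w = self, weight
        N, C, L = a.data.shape
        O, Cw, k = w.data.shape
        if Cw != C:
            raise ValueError(f"weight expects {Cw} channels, input has {C}")
        xp = np.pad(a.data, ((0, 0), (0, 0), (padding, padding)))
        win = sliding_window_view(xp, k, axis=2)[:, :, ::stride]
        Lo = win.shape[2]
        out = np.einsum("nclk,ock->nol", win, w.data, optimize=True)
        if bias is not None:
            out = out + bias.data.reshape(1, O, 1)
        parents = (a, w) if bias is None else (a, w, bias)

        def backward(g):
            if w.requires_grad:
                w._accum(np.einsum("nol,nclk->ock", g, win, optimize=True))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)))
            if a.requires_grad:
                gwin = np.einsum("nol,ock->nclk", g, w.data, optimize=True)
                gxp = np.zeros_like(xp)
                for y in range(k):
                    gxp[:, :, y:y + Lo * stride:stride] += gwin[:, :, :, y]
                if padding:
                    gxp = gxp[:, :, padding:padding + L]
                a._accum(gxp)

        return Tensor._from_op(out, parents, backward)

    def max_pool1d(self, k: int = 2):
        """Non-overlapping max pooling over the last axis (truncates remainder)."""
        a = self
        N, C, L = a.data.shape
        Lo = L // k
        blocks = a.data[:, :, : Lo * k].reshape(N, C, Lo, k)
        idx = blocks.argmax(axis=3)

        def backward(g):
            gx = np.zeros((N, C, Lo, k))
            np.put_along_axis(gx, idx[..., None], g[..., None], axis=3)
            full = np.zeros_like(a.data)
            full[:, :, : Lo * k] = gx.reshape(N, C, Lo * k)
            a._accum(full)

        return Tensor._from_op(blocks.max(axis=3), (a,), backward)


# -- softmax family -----------------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    a = Tensor._lift(x)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        a._accum(out * (g - (g * out).sum(axis=axis, keepdims=True)))

    return Tensor._from_op(out, (a,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    a = Tensor._lift(x)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    out = z - np.log(np.exp(z).sum(axis=axis, keepdims=True))

    def backward(g):
        a._accum(g - np.exp(out) * g.sum(axis=axis, keepdims=True))

    return Tensor._from_op(out, (a,), backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy from raw scores and integer labels."""
    labels = np.asarray(labels)
    n, c = logits.shape
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"label outside [0, {c})")
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    ls = log_softmax(logits, axis=-1)
    return -(ls * Tensor(onehot)).sum() / float(n)
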
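"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The restoration network and its adversarial training loop need gradients of
scalar losses with respect to convolution weights, attention temperatures and
gates.  This module provides exactly the primitives those models use — no
more: elementwise arithmetic, matmul, reductions, 2-D (grouped) convolution,
a masked row-softmax, and an l1 penalty on the 2-D discrete Fourier
transform.  Everything is float64 and single-sample (no batch axis), which
keeps runs bit-reproducible on CPU.

Graphs are built eagerly; ``Tensor.backward()`` runs a topological sweep and
accumulates ``.grad`` on every tensor with ``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "masked_softmax",
    "fourier_l1",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        p = float(p)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * p * np.power(a.data, p - 1.0))

        return Tensor._make(np.power(self.data, p), (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ np.swapaxes(b.data, -1, -2))
            if b.requires_grad:
                b._accum(np.swapaxes(a.data, -1, -2) @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self, idx=idx):
            if a.requires_grad:
                full = np.zeros(a.shape)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- reductions & elementwise --------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def abs(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * np.sign(a.data))

        return Tensor._make(np.abs(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * 0.5 / o)

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * (a.data > 0.0))

        return Tensor._make(np.maximum(self.data, 0.0), (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        def backward(g, a=self, slope=slope):
            if a.requires_grad:
                a._accum(g * np.where(a.data > 0.0, 1.0, slope))

        return Tensor._make(
            np.where(self.data > 0.0, self.data, slope * self.data), (self,), backward
        )

    # -- internals ------------------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accum(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis`."""
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, offs=offsets, axis=axis):
        for i, t in enumerate(ts):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(int(offs[i]), int(offs[i + 1]))
                t._accum(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation on a (C, H, W) tensor.

    `w` has shape (C_out, C_in // groups, kh, kw); `groups == C_in` gives a
    depth-wise convolution.  Forward and backward use an im2col layout so the
    heavy lifting is a per-group matmul.
    """
    C, H, W = x.shape
    Co, Cig, kh, kw = w.shape
    if C % groups or Co % groups or Cig != C // groups:
        raise ValueError(
            f"inconsistent conv groups: x has {C} channels, w {w.shape}, groups={groups}"
        )
    s, p = int(stride), int(padding)
    if kh == 1 and kw == 1 and s == 1 and p == 0 and groups == 1:
        return _conv1x1(x, w, b)
    if groups == C and Co == C:
        return _conv_depthwise(x, w, b, s, p)
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = xp.shape[1:]
    Ho = (Hp - kh) // s + 1
    Wo = (Wp - kw) // s + 1
    # (C, Ho, Wo, kh, kw) view, then (groups, Cig*kh*kw, Ho*Wo) matrix
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))[:, ::s, ::s]
    cols = np.ascontiguousarray(win.transpose(0, 3, 4, 1, 2)).reshape(
        groups, Cig * kh * kw, Ho * Wo
    )
    w_mat = w.data.reshape(groups, Co // groups, Cig * kh * kw)
    out = (w_mat @ cols).reshape(Co, Ho, Wo)
    if b is not None:
        out = out + b.data.reshape(Co, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g_mat = g.reshape(groups, Co // groups, Ho * Wo)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(1, 2)))
        if w.requires_grad:
            gw = g_mat @ cols.transpose(0, 2, 1)
            w._accum(gw.reshape(Co, Cig, kh, kw))
        if x.requires_grad:
            gcols = (w_mat.transpose(0, 2, 1) @ g_mat).reshape(C, kh, kw, Ho, Wo)
            gxp = np.zeros((C, Hp, Wp))
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i : i + Ho * s : s, j : j + Wo * s : s] += gcols[:, i, j]
            x._accum(gxp[:, p : Hp - p, p : Wp - p] if p else gxp)

    return Tensor._make(out, parents, backward)


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Pointwise convolution as a single matmul."""
    C, H, W = x.shape
    Co = w.shape[0]
    w2 = w.data.reshape(Co, C)
    xm = x.data.reshape(C, H * W)
    out = (w2 @ xm).reshape(Co, H, W)
    if b is not None:
        out += b.data[:, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gm = g.reshape(Co, H * W)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(1, 2)))
        if w.requires_grad:
            w._accum((gm @ xm.T).reshape(w.shape))
        if x.requires_grad:
            x._accum((w2.T @ gm).reshape(C, H, W))

    return Tensor._make(out, parents, backward)


def _conv_depthwise(x: Tensor, w: Tensor, b: Tensor | None, s: int, p: int) -> Tensor:
    """Depth-wise convolution as k*k shifted fused multiply-adds."""
    C, H, W = x.shape
    kh, kw = w.shape[2:]
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = xp.shape[1:]
    Ho = (Hp - kh) // s + 1
    Wo = (Wp - kw) // s + 1
    out = np.zeros((C, Ho, Wo))
    for i in range(kh):
        for j in range(kw):
            out += w.data[:, 0, i, j, None, None] * xp[:, i : i + Ho * s : s, j : j + Wo * s : s]
    if b is not None:
        out += b.data[:, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(1, 2)))
        if w.requires_grad:
            gw = np.empty(w.shape)
            for i in range(kh):
                for j in range(kw):
                    gw[:, 0, i, j] = (g * xp[:, i : i + Ho * s : s, j : j + Wo * s : s]).sum(
                        axis=(1, 2)
                    )
            w._accum(gw)
        if x.requires_grad:
            gxp = np.zeros((C, Hp, Wp))
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i : i + Ho * s : s, j : j + Wo * s : s] += (
                        w.data[:, 0, i, j, None, None] * g
                    )
            x._accum(gxp[:, p : Hp - p, p : Wp - p] if p else gxp)

    return Tensor._make(out, parents, backward)


def masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax over the last axis, restricted to `mask` entries.

    Masked-out positions get probability exactly 0; each row's retained
    entries sum to 1 (every row must retain at least one entry).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != scores.shape:
        raise ValueError("mask shape must match scores shape")
    if not mask.any(axis=-1).all():
        raise ValueError("every row must retain at least one entry")
    neg = np.where(mask, scores.data, -np.inf)
    m = neg.max(axis=-1, keepdims=True)
    e = np.exp(neg - m)
    e[~mask] = 0.0
    y = e / e.sum(axis=-1, keepdims=True)

    def backward(g, s=scores, y=y):
        if s.requires_grad:
            inner = (g * y).sum(axis=-1, keepdims=True)
            s._accum(y * (g - inner))

    return Tensor._make(y, (scores,), backward)


def fourier_l1(r: Tensor, reduction: str = "sum") -> Tensor:
    """l1 norm of the unnormalized 2-D DFT of `r` (last two axes).

    For a real residual r, d/dr sum|F r| = N * Re(ifft2(sign(F r))) with
    N = H * W, which is what the backward pass applies.
    """
    if reduction not in ("sum", "mean"):
        raise ValueError("reduction must be 'sum' or 'mean'")
    F = np.fft.fft2(r.data, axes=(-2, -1))
    mag = np.abs(F)
    total = mag.sum()
    n_total = r.size
    value = total / n_total if reduction == "mean" else total

    def backward(g, r=r, F=F, mag=mag):
        if not r.requires_grad:
            return
        with np.errstate(invalid="ignore", divide="ignore"):
            sgn = np.where(mag > 0.0, F / mag, 0.0)
        hw = r.shape[-2] * r.shape[-1]
        grad = hw * np.real(np.fft.ifft2(sgn, axes=(-2, -1)))
        if reduction == "mean":
            grad = grad / n_total
        r._accum(float(g) * grad)

    return Tensor._make(np.float64(value), (r,), backward)
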
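"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the fusion network needs: broadcast
arithmetic, matmul, ReLU/sigmoid/exp/log, power, reductions, reshape,
concatenation, 2D convolution (im2col), nearest-neighbor upsampling and
clamping. Float64 throughout, so finite-difference gradient checks are tight.

Guided backpropagation (for fine-grained saliency) is a global mode that makes
every ReLU suppress negative upstream gradients during the backward pass.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GUIDED = [False]


@contextmanager
def guided_backprop():
    """Within this context, ReLU backward passes only positive gradients."""
    _GUIDED[0] = True
    try:
        yield
    finally:
        _GUIDED[0] = False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------------ graph

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        """Accumulate gradients of this (scalar or given-grad) node into leaves."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** (-1.0)

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * e * self.data ** (e - 1.0))

        return self._make(self.data**e, (self,), bw)

    def matmul(self, other: "Tensor"):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    __matmul__ = matmul

    # ------------------------------------------------------------ nonlinear

    def relu(self):
        pos = self.data > 0

        def bw(g):
            if self.requires_grad:
                grad = g * pos
                if _GUIDED[0]:
                    grad = grad * (g > 0)
                self._accumulate(grad)

        return self._make(np.where(pos, self.data, 0.0), (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        return self._make(s, (self,), bw)

    def exp(self):
        e = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * e)

        return self._make(e, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def clamp_min(self, lo: float):
        keep = self.data >= lo

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * keep)

        return self._make(np.maximum(self.data, lo), (self,), bw)

    def clamp_max(self, hi: float):
        keep = self.data <= hi

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * keep)

        return self._make(np.minimum(self.data, hi), (self,), bw)

    # ------------------------------------------------------------ reductions

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------- shape ops

    def reshape(self, *shape):
        old = self.shape

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), bw)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(out_data, requires_grad=any(t.requires_grad for t in tensors))

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """2D convolution: x (B,C,H,W), w (O,C,kh,kw), b (O,)."""
    B, C, H, W = x.data.shape
    O, _, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B,C,Ho,Wo,kh,kw)
    Ho, Wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho, Wo, C * kh * kw)
    wmat = w.data.reshape(O, -1)
    out_data = cols @ wmat.T + b.data  # (B,Ho,Wo,O)
    out_data = out_data.transpose(0, 3, 1, 2)
    out = Tensor(out_data, requires_grad=x.requires_grad or w.requires_grad or b.requires_grad)

    def bw(g):
        g_rs = g.transpose(0, 2, 3, 1)  # (B,Ho,Wo,O)
        if b.requires_grad:
            b._accumulate(g_rs.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            dw = g_rs.reshape(-1, O).T @ cols.reshape(-1, C * kh * kw)
            w._accumulate(dw.reshape(w.data.shape))
        if x.requires_grad:
            dcols = (g_rs @ wmat).reshape(B, Ho, Wo, C, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + Ho * stride : stride, j : j + Wo * stride : stride] += (
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            if pad:
                dxp = dxp[:, :, pad:-pad, pad:-pad]
            x._accumulate(dxp)

    if out.requires_grad:
        out._parents = (x, w, b)
        out._backward = bw
    return out


def upsample_nearest(x: Tensor, scale: int) -> Tensor:
    """Nearest-neighbor spatial upsampling by an integer factor."""
    B, C, H, W = x.data.shape
    out_data = np.repeat(np.repeat(x.data, scale, axis=2), scale, axis=3)
    out = Tensor(out_data, requires_grad=x.requires_grad)

    def bw(g):
        if x.requires_grad:
            x._accumulate(
                g.reshape(B, C, H, scale, W, scale).sum(axis=(3, 5))
            )

    if out.requires_grad:
        out._parents = (x,)
        out._backward = bw
    return out
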
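"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations needed by the two-stage encoder and its
self-supervised objectives: broadcasting arithmetic, matmul, reductions,
elementwise nonlinearities, reshaping, 2-D convolution (via im2col) and
overlapping max pooling. Gradients are accumulated by a topological-order
sweep from the output scalar. ``Tensor.detach`` severs the graph, which is
how gradient isolation between encoder stages is enforced.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        """Return a view of the data with no graph history (stop-gradient)."""
        return Tensor(self.data, requires_grad=False)

    # -- graph machinery -----------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            if a.requires_grad or a._parents:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad or b._parents:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, a=self):
            a._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            if a.requires_grad or a._parents:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad or b._parents:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            if a.requires_grad or a._parents:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad or b._parents:
                b._accumulate(_unbroadcast(-g * a.data / b.data**2, b.shape))

        return Tensor(self.data / other.data, parents=(self, other), backward=bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def bw(g, a=self, p=exponent):
            a._accumulate(g * p * a.data ** (p - 1))

        return Tensor(self.data**exponent, parents=(self,), backward=bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")

        def bw(g, a=self, b=other):
            if a.requires_grad or a._parents:
                a._accumulate(g @ b.data.T)
            if b.requires_grad or b._parents:
                b._accumulate(a.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    # -- elementwise ---------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g, a=self, o=out_data):
            a._accumulate(g * o)

        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self):
        def bw(g, a=self):
            a._accumulate(g / a.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g, a=self, o=out_data):
            a._accumulate(g * 0.5 / o)

        return Tensor(out_data, parents=(self,), backward=bw)

    def relu(self):
        mask = self.data > 0

        def bw(g, a=self, m=mask):
            a._accumulate(g * m)

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.data.shape

        def bw(g, a=self, s=old_shape):
            a._accumulate(g.reshape(s))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=bw)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bw(g, a=self, inv=inv):
            a._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=bw)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        shape = self.data.shape

        def bw(g, a=self, axis=axis, keepdims=keepdims, shape=shape):
            if axis is None:
                grad = np.broadcast_to(g, shape)
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                grad = np.broadcast_to(g, shape)
            a._accumulate(grad)

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bw
        )

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in ax]))
            if isinstance(axis, tuple):
                # reduce iteratively for tuple axes via sum
                return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- structured ops ------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor", stride: int, padding: int):
        """2-D convolution (cross-correlation), NCHW layout, square kernel."""
        x, w = self.data, weight.data
        n_batch, c_in, h, wdt = x.shape
        c_out, c_in_w, kh, kw = w.shape
        if c_in != c_in_w:
            raise ValueError(f"channel mismatch: input {c_in}, kernel {c_in_w}")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        hp, wp = xp.shape[2], xp.shape[3]
        oh = (hp - kh) // stride + 1
        ow = (wp - kw) // stride + 1
        if oh <= 0 or ow <= 0:
            raise ValueError(
                f"spatial collapse: input {h}x{wdt} with kernel {kh}, "
                f"stride {stride}, padding {padding} yields {oh}x{ow}"
            )
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]  # (B, C, oh, ow, kh, kw)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n_batch * oh * ow, c_in * kh * kw)
        wflat = w.reshape(c_out, c_in * kh * kw)
        out = cols @ wflat.T + bias.data[None, :]
        out = out.reshape(n_batch, oh, ow, c_out).transpose(0, 3, 1, 2)

        def bw(g, a=self, wt=weight, bt=bias, cols=cols, wflat=wflat):
            gf = g.transpose(0, 2, 3, 1).reshape(n_batch * oh * ow, c_out)
            if bt.requires_grad or bt._parents:
                bt._accumulate(gf.sum(axis=0))
            if wt.requires_grad or wt._parents:
                wt._accumulate((gf.T @ cols).reshape(c_out, c_in, kh, kw))
            if a.requires_grad or a._parents:
                dcols = (gf @ wflat).reshape(n_batch, oh, ow, c_in, kh, kw)
                dxp = np.zeros((n_batch, c_in, hp, wp))
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += (
                            dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                        )
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                a._accumulate(dxp)

        return Tensor(out, parents=(self, weight, bias), backward=bw)

    def maxpool2d(self, kernel: int, stride: int):
        x = self.data
        n_batch, c, h, w = x.shape
        oh = (h - kernel) // stride + 1
        ow = (w - kernel) // stride + 1
        if oh <= 0 or ow <= 0:
            raise ValueError(
                f"spatial collapse: {h}x{w} input with pool kernel {kernel}, stride {stride}"
            )
        win = np.lib.stride_tricks.sliding_window_view(x, (kernel, kernel), axis=(2, 3))
        win = win[:, :, ::stride, ::stride].reshape(n_batch, c, oh, ow, kernel * kernel)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

        def bw(g, a=self, idx=idx):
            di, dj = idx // kernel, idx % kernel
            bi, ci, oy, ox = np.indices((n_batch, c, oh, ow))
            rows = oy * stride + di
            cols_ = ox * stride + dj
            flat = ((bi * c + ci) * h + rows) * w + cols_
            dx = np.zeros(n_batch * c * h * w)
            np.add.at(dx, flat.ravel(), g.ravel())
            a._accumulate(dx.reshape(n_batch, c, h, w))

        return Tensor(out, parents=(self,), backward=bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
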
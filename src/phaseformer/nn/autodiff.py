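"""A compact tape-based reverse-mode automatic differentiation engine.

Sized for this package's model: dense float64 numpy arrays, a fixed set of
primitives (arithmetic, matmul, reshape/transpose/concat, ReLU/tanh/exp,
reductions, softmax, 3D convolution), dynamic graphs, and scalar-rooted
backpropagation. Convolution is implemented by window extraction (im2col)
so its gradient is a pair of matrix products plus a scatter-add.

Gradients of every primitive are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "conv3d", "softmax", "layer_norm"]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to the original operand shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        # float32 and float64 are both supported; dtype propagates through ops
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    def _wrap(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        # match our dtype so python scalars don't upcast float32 graphs
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            a._accumulate(_sum_to_shape(g, a.shape))
            b._accumulate(_sum_to_shape(g, b.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            a._accumulate(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            a._accumulate(_sum_to_shape(g * b.data, a.shape))
            b._accumulate(_sum_to_shape(g * a.data, b.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        data = self.data ** exponent

        def backward(g, a=self, e=exponent, d=data):
            a._accumulate(g * e * a.data ** (e - 1.0))

        return Tensor._from_op(data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            a._accumulate(_sum_to_shape(ga, a.shape))
            b._accumulate(_sum_to_shape(gb, b.shape))

        return Tensor._from_op(np.matmul(self.data, other.data), (self, other), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g, a=self, old=old):
            a._accumulate(g.reshape(old))

        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)

        def backward(g, a=self, inv=tuple(inverse)):
            a._accumulate(g.transpose(inv))

        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            a._accumulate(g * m)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.1):
        slope = self.data.dtype.type(slope)
        factor = np.where(self.data > 0, self.data.dtype.type(1.0), slope)

        def backward(g, a=self, f=factor):
            a._accumulate(g * f)

        return Tensor._from_op(self.data * factor, (self,), backward)

    def tanh(self):
        data = np.tanh(self.data)

        def backward(g, a=self, d=data):
            a._accumulate(g * (1.0 - d * d))

        return Tensor._from_op(data, (self,), backward)

    def exp(self):
        data = np.exp(self.data)

        def backward(g, a=self, d=data):
            a._accumulate(g * d)

        return Tensor._from_op(data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return Tensor._from_op(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    # -- autodiff driver ------------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from a scalar output."""
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
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tuple(tensors), offs=offsets, axis=axis):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g, a=x, p=p, axis=axis):
        dot = np.sum(g * p, axis=axis, keepdims=True)
        a._accumulate(p * (g - dot))

    return Tensor._from_op(p, (x,), backward)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Normalize over the last axis; composed from primitives."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    inv = (var + eps) ** -0.5
    return centered * inv * gain + bias


def _im2col(xp: np.ndarray, kernel: tuple[int, int, int]) -> np.ndarray:
    """(B, C, D+pd, H+ph, W+pw) -> (B, D*H*W, C*kd*kh*kw) window matrix."""
    win = sliding_window_view(xp, kernel, axis=(2, 3, 4))
    b, c, d, h, w = win.shape[:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(b, d * h * w, -1)
    return np.ascontiguousarray(cols), (d, h, w)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """3D convolution (cross-correlation), stride 1, zero 'same' padding.

    x: (B, Cin, D, H, W); weight: (Cout, Cin, kd, kh, kw); bias: (Cout,).
    Output: (B, Cout, D, H, W).
    """
    b, cin, d, h, w = x.shape
    cout, cin_w, kd, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"conv3d channel mismatch: {cin} vs {cin_w}")
    pads = (kd // 2, kh // 2, kw // 2)
    xp = np.pad(x.data, ((0, 0), (0, 0)) + tuple((p, p) for p in pads))
    cols, _ = _im2col(xp, (kd, kh, kw))
    wmat = weight.data.reshape(cout, -1).T  # (Cin*k3, Cout)
    out = cols @ wmat + bias.data  # (B, DHW, Cout)
    out = out.transpose(0, 2, 1).reshape(b, cout, d, h, w)

    def backward(g, x=x, weight=weight, bias=bias, cols=cols, wmat=wmat,
                 dims=(b, cin, d, h, w), kernel=(kd, kh, kw), pads=pads):
        b_, cin_, d_, h_, w_ = dims
        kd_, kh_, kw_ = kernel
        gout = g.reshape(b_, -1, d_ * h_ * w_).transpose(0, 2, 1)  # (B, DHW, Cout)
        bias._accumulate(gout.sum(axis=(0, 1)))
        gw = np.einsum("bnk,bnc->ck", cols, gout)  # (Cout, Cin*k3)
        weight._accumulate(gw.reshape(weight.shape))
        if x.requires_grad:
            gcols = gout @ wmat.T  # (B, DHW, Cin*k3)
            gcols = gcols.reshape(b_, d_, h_, w_, cin_, kd_, kh_, kw_)
            gxp = np.zeros((b_, cin_, d_ + 2 * pads[0], h_ + 2 * pads[1],
                            w_ + 2 * pads[2]), dtype=x.data.dtype)
            for a in range(kd_):
                for bb in range(kh_):
                    for cc in range(kw_):
                        gxp[:, :, a:a + d_, bb:bb + h_, cc:cc + w_] += \
                            gcols[:, :, :, :, :, a, bb, cc].transpose(0, 4, 1, 2, 3)
            x._accumulate(gxp[:, :, pads[0]:pads[0] + d_,
                              pads[1]:pads[1] + h_, pads[2]:pads[2] + w_])

    return Tensor._from_op(out, (x, weight, bias), backward)
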
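"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: every operation builds a node whose
``_backward`` closure accumulates gradients into its parents.  Arrays are kept
in float32; convolution is realised through im2col buffers that are recomputed
during the backward pass instead of cached, which keeps peak memory bounded by
the activations alone.  The op set is exactly what the encoder-decoder
segmentation networks and their losses need: elementwise arithmetic,
reductions, matmul, 2-D convolution with arbitrary padding, 2x2 stride-2
transposed convolution, 2x2 max pooling, nearest-neighbour 2x upsampling and
channel concatenation.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(DTYPE, copy=False)
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction helper -------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
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

    def _accum(self, grad):
        if self.grad is None:
            self.grad = grad.astype(DTYPE, copy=False)
        else:
            self.grad = self.grad + grad

    # -- autodiff driver -----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # free interior gradients eagerly
                if node is not self:
                    node.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._from_op(data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._from_op(data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._from_op(data, (self,), backward)

    # -- transcendental -------------------------------------------------------
    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * data)

        return Tensor._from_op(data, (self,), backward)

    def log(self):
        data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._from_op(data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def sigmoid(self):
        # piecewise-stable logistic (avoids exp overflow for large |x|)
        x = self.data
        data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(DTYPE)

        def backward(g):
            if self.requires_grad:
                self._accum(g * data * (1.0 - data))

        return Tensor._from_op(data, (self,), backward)

    def relu(self):
        data = np.maximum(self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        return Tensor._from_op(data, (self,), backward)

    def leaky_relu(self, slope: float = 0.01):
        data = np.where(self.data > 0, self.data, slope * self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * np.where(self.data > 0, 1.0, slope).astype(DTYPE))

        return Tensor._from_op(data, (self,), backward)

    def clip_eps(self, eps: float):
        """Clip to [eps, 1-eps] with zero gradient outside (log guard)."""
        data = np.clip(self.data, eps, 1.0 - eps)

        def backward(g):
            if self.requires_grad:
                inside = (self.data >= eps) & (self.data <= 1.0 - eps)
                self._accum(g * inside)

        return Tensor._from_op(data, (self,), backward)

    def clip01(self):
        """Clip to [0, 1] with zero gradient outside the interval."""
        data = np.clip(self.data, 0.0, 1.0)

        def backward(g):
            if self.requires_grad:
                inside = (self.data >= 0.0) & (self.data <= 1.0)
                self._accum(g * inside)

        return Tensor._from_op(data, (self,), backward)

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).astype(DTYPE))
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, self.shape).astype(DTYPE))

        return Tensor._from_op(data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        data = self.data.reshape(*shape)
        orig = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._from_op(data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._from_op(data, (self, other), backward)


# -- structural ops -----------------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate along ``axis`` (used for skip connections)."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    return Tensor._from_op(data, tuple(tensors), backward)


def _pad_hw(x: np.ndarray, pt: int, pb: int, pl: int, pr: int) -> np.ndarray:
    if pt == pb == pl == pr == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))


def _im2col(xp: np.ndarray, kh: int, kw: int, ho: int, wo: int) -> np.ndarray:
    n, c = xp.shape[:2]
    col = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            col[:, :, i, j] = xp[:, :, i:i + ho, j:j + wo]
    return col


def conv2d(x: Tensor, w: Tensor, b: Tensor, padding) -> Tensor:
    """Stride-1 2-D convolution, NCHW layout.

    ``padding`` is (top, bottom, left, right); 3x3 kernels use (1,1,1,1),
    1x1 kernels (0,0,0,0) and 10x10 kernels the asymmetric (4,5,4,5) so that
    spatial size is preserved.
    """
    pt, pb, pl, pr = padding
    cout, cin, kh, kw = w.shape
    xp = _pad_hw(x.data, pt, pb, pl, pr)
    ho = xp.shape[2] - kh + 1
    wo = xp.shape[3] - kw + 1
    col = _im2col(xp, kh, kw, ho, wo)
    # (N,C,kh,kw,Ho,Wo) x (Cout,C,kh,kw) -> (N,Ho,Wo,Cout)
    out = np.tensordot(col, w.data, axes=([1, 2, 3], [1, 2, 3]))
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    out += b.data.reshape(1, -1, 1, 1)
    del col

    def backward(g):
        xp2 = _pad_hw(x.data, pt, pb, pl, pr)
        col2 = _im2col(xp2, kh, kw, ho, wo)
        if w.requires_grad:
            # (N,Cout,Ho,Wo) x (N,C,kh,kw,Ho,Wo) -> (Cout,C,kh,kw)
            w._accum(np.tensordot(g, col2, axes=([0, 2, 3], [0, 4, 5])))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        del col2
        if x.requires_grad:
            # (N,Cout,Ho,Wo) x (Cout,C,kh,kw) -> (N,Ho,Wo,C,kh,kw)
            dcol = np.tensordot(g, w.data, axes=([1], [0]))
            dxp = np.zeros_like(xp2)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + ho, j:j + wo] += dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            h, wd = x.shape[2], x.shape[3]
            x._accum(dxp[:, :, pt:pt + h, pl:pl + wd])

    return Tensor._from_op(out, (x, w, b), backward)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2 stride-2 transposed convolution (exact spatial doubling).

    Kernel layout (Cin, Cout, 2, 2); with stride equal to kernel size the
    output patches do not overlap, so the op is a per-pixel linear map
    followed by a 2x2 block rearrangement.
    """
    n, cin, h, wd = x.shape
    cout = w.shape[1]
    # (N,Cin,H,W) x (Cin,Cout,2,2) -> (N,H,W,Cout,2,2)
    t = np.tensordot(x.data, w.data, axes=([1], [0]))
    out = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, cout, 2 * h, 2 * wd)
    out = np.ascontiguousarray(out)
    out += b.data.reshape(1, -1, 1, 1)

    def backward(g):
        gb = g.reshape(n, cout, h, 2, wd, 2).transpose(0, 2, 4, 1, 3, 5)
        if w.requires_grad:
            # (N,Cin,H,W) x (N,H,W,Cout,2,2) -> (Cin,Cout,2,2)
            w._accum(np.tensordot(x.data, gb, axes=([0, 2, 3], [0, 1, 2])))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # (N,H,W,Cout,2,2) x (Cin,Cout,2,2) -> (N,H,W,Cin)
            dx = np.tensordot(gb, w.data, axes=([3, 4, 5], [1, 2, 3]))
            x._accum(np.ascontiguousarray(dx.transpose(0, 3, 1, 2)))

    return Tensor._from_op(out, (x, w, b), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, wd = x.shape
    ho, wo = h // 2, wd // 2
    xr = x.data.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dxr = np.zeros((n, c, ho, wo, 4), dtype=DTYPE)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, wd)
        x._accum(dx)

    return Tensor._from_op(out, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour spatial doubling (used to resample attention maps)."""
    data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, wd = x.shape

    def backward(g):
        if x.requires_grad:
            x._accum(g.reshape(n, c, h, 2, wd, 2).sum(axis=(3, 5)))

    return Tensor._from_op(data, (x,), backward)
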
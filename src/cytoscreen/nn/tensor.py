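"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the segmentation and classification
networks need: broadcasting arithmetic, (batched) matrix multiplication,
2-D convolution via im2col, 2x2 max pooling, nearest-neighbour 2x
upsampling, channel concatenation, reductions and pointwise
nonlinearities.  Gradients are accumulated with a topological sweep.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad only on scalars")
            grad = np.ones_like(self.data)
        # iterative postorder: no recursion limit, and no self-referential
        # closure keeping the whole graph alive until a full gc pass
        topo, seen = [], set()
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
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def detach(self):
        return Tensor(self.data)

    def item(self):
        return float(self.data)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = Tensor(self.data + other.data, parents=_active(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=_active(self))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.data.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = Tensor(self.data * other.data, parents=_active(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = Tensor(self.data / other.data, parents=_active(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other, self.data.dtype) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=_active(self))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = Tensor(self.data @ other.data, parents=_active(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad or other._parents:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    # -- pointwise -----------------------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=_active(self))
        out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=_active(self))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, parents=_active(self))
        out._backward = lambda g: self._accum(g * 0.5 / y)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=_active(self))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=_active(self))
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the un-clamped region."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), parents=_active(self))
        out._backward = lambda g: self._accum(g * mask)
        return out

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), parents=_active(self))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), parents=_active(self))
        out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=_active(self))

        def bw(g):
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def _as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if dtype is not None and arr.dtype != dtype and np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(dtype)
    elif dtype is not None and not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(dtype)
    return Tensor(arr)


def _active(*tensors):
    return tuple(t for t in tensors if t.requires_grad or t._parents)


# ---------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------

def concat(tensors, axis=1):
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=_active(*tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int | None = None):
    """2-D convolution (cross-correlation), stride 1, NCHW layout.

    x: (N, C, H, W); w: (F, C, kh, kw); default 'same' padding kh//2.
    Computed as a sum of per-offset tensor contractions so no im2col
    matrix is materialized or retained for the backward pass.
    """
    N, C, H, W = x.data.shape
    F, Cw, kh, kw = w.data.shape
    assert C == Cw, "channel mismatch"
    pad = kh // 2 if padding is None else padding

    def padded(a):
        if pad == 0:
            return a
        return np.pad(a, ((0, 0), (0, 0), (pad, pad), (pad, pad)))

    xp = padded(x.data)
    Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    y = np.zeros((N, Ho, Wo, F), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            # (N,C,Ho,Wo) x (F,C) -> (N,Ho,Wo,F)
            y += np.tensordot(xp[:, :, i : i + Ho, j : j + Wo], w.data[:, :, i, j],
                              axes=([1], [1]))
    if b is not None:
        y += b.data
    del xp
    parents = _active(x, w) if b is None else _active(x, w, b)
    out = Tensor(np.ascontiguousarray(y.transpose(0, 3, 1, 2)), parents=parents)

    def bw(g):
        gout = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # N,Ho,Wo,F
        if b is not None and (b.requires_grad or b._parents):
            b._accum(gout.sum(axis=(0, 1, 2)))
        need_x = x.requires_grad or x._parents
        need_w = w.requires_grad or w._parents
        if not (need_x or need_w):
            return
        xpb = padded(x.data) if need_w else None
        dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=x.data.dtype) if need_x else None
        dw = np.zeros_like(w.data) if need_w else None
        for i in range(kh):
            for j in range(kw):
                if need_w:
                    dw[:, :, i, j] = np.tensordot(
                        gout, xpb[:, :, i : i + Ho, j : j + Wo],
                        axes=([0, 1, 2], [0, 2, 3]),
                    )
                if need_x:
                    dxp[:, :, i : i + Ho, j : j + Wo] += np.tensordot(
                        gout, w.data[:, :, i, j], axes=([3], [0])
                    ).transpose(0, 3, 1, 2)
        if need_w:
            w._accum(dw)
        if need_x:
            x._accum(dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp)

    out._backward = bw
    return out


def maxpool2(x: Tensor):
    """2x2 max pooling, stride 2; H and W must be even."""
    N, C, H, W = x.data.shape
    assert H % 2 == 0 and W % 2 == 0, "maxpool2 needs even spatial dims"
    r = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    y = r.max(axis=(3, 5))
    out = Tensor(y, parents=_active(x))
    # mask of (first) argmax per 2x2 block; ties split the gradient
    expand = np.repeat(np.repeat(y, 2, axis=2), 2, axis=3)
    mask = (x.data == expand)
    counts = mask.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))

    def bw(g):
        ge = np.repeat(np.repeat(g / counts, 2, axis=2), 2, axis=3)
        x._accum(ge * mask)

    out._backward = bw
    return out


def upsample2(x: Tensor):
    """Nearest-neighbour 2x spatial upsampling."""
    y = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor(y, parents=_active(x))
    N, C, H, W = x.data.shape

    def bw(g):
        x._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    out._backward = bw
    return out


def global_avg_pool(x: Tensor):
    """(N, C, H, W) -> (N, C)."""
    return x.mean(axis=(2, 3))


def softmax(x: Tensor, axis: int = 1):
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant shift
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = 1):
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()
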
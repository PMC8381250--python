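"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray``,
records the operations that produced it, and :meth:`Tensor.backward`
replays them in reverse topological order.  Only the operations needed
by a 2D encoder–decoder segmentation network are provided — elementwise
arithmetic with broadcasting, matmul, reductions, 3×3 "same" convolution,
2×2 max-pooling, nearest-neighbour upsampling, concatenation and the
usual activations.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
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


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager: ops inside build no graph (inference mode)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_bw", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED[0]
        self._bw = None
        # a graph edge is only useful if a gradient will flow through it
        self._parents = _parents if self.requires_grad else ()

    @property
    def _backward(self):
        return self._bw

    @_backward.setter
    def _backward(self, fn):
        # dropping the closure when nothing upstream needs a gradient
        # breaks the out->closure->out reference cycle and frees memory
        self._bw = fn if self._parents else None

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g):
        dtype = np.result_type(self.data, np.float32)
        if self.grad is None:
            self.grad = np.array(g, dtype=dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None, free_graph: bool = True):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen, stack = [], set(), [(self, False)]
        while stack:                       # iterative DFS: deep graphs, no recursion limit
            t, done = stack.pop()
            if done:
                topo.append(t)
                continue
            if id(t) in seen:
                continue
            seen.add(id(t))
            stack.append((t, True))
            stack.extend((p, False) for p in t._parents)

        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._bw is not None and t.grad is not None:
                t._bw(t.grad)
            if free_graph and t._parents:
                # interior node: closure and grad are no longer needed;
                # clearing them breaks reference cycles and frees memory
                # promptly.  Leaf grads (parameters) are kept for the
                # optimizer.
                t._bw = None
                t._parents = ()
                if t is not self:
                    t.grad = None

    # -- elementwise arithmetic ---------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):     # keep float32 graphs float32
            out = Tensor(self.data + other, self.requires_grad, (self,))

            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.data.shape))
            out._backward = bw
            return out
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data * other, self.requires_grad, (self,))

            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other, self.data.shape))
            out._backward = bw
            return out
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return (-self) + other

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** (-1.0)

    def __pow__(self, p: float):
        # np.power with float exponents is slow; special-case common ones
        if p == 2.0:
            d = self.data * self.data
        elif p == 0.5:
            d = np.sqrt(self.data)
        elif p == -0.5:
            d = 1.0 / np.sqrt(self.data)
        elif p == -1.0:
            d = 1.0 / self.data
        else:
            d = self.data ** p
        out = Tensor(d, self.requires_grad, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if p == 2.0:
                self._accum(g * (2.0 * self.data))
            elif p == -1.0:
                self._accum(-g * out.data * out.data)
            elif p == -0.5:
                self._accum(-0.5 * g * out.data / self.data)
            elif p == 0.5:
                self._accum(0.5 * g / out.data)
            else:
                self._accum(g * p * self.data ** (p - 1.0))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        out._backward = bw
        return out

    # -- unary ---------------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out.data)
        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))
        out._backward = bw
        return out

    def sigmoid(self):
        from scipy.special import expit

        out = Tensor(expit(self.data), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out.data * (1.0 - out.data))
        out._backward = bw
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def amax(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.max(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            expanded = out.data if keepdims or axis is None else np.expand_dims(out.data, axis)
            mask = (self.data == expanded)
            if axis is None:
                gg = g
            elif not keepdims:
                gg = np.expand_dims(g, axis)
            else:
                gg = g
            self._accum(mask * gg)
        out._backward = bw
        return out

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))
        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])
    out._backward = bw
    return out


def softmax(x: Tensor, axis) -> Tensor:
    """Numerically stable softmax along `axis` (int or tuple)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant w.r.t. grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'Same' 2D convolution (cross-correlation) for odd kernels.

    x: (N, C, H, W); w: (Cout, C, kh, kw); b: (Cout,).
    """
    N, C, H, W = x.data.shape
    Co, Ci, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input has {C}, kernel expects {Ci}")
    ph, pw = kh // 2, kw // 2
    dtype = x.data.dtype
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    # im2col in a (C, kh, kw, N*H*W) layout: the per-offset slices copy
    # large contiguous blocks, and the GEMM contracts the leading axis
    cols = np.empty((C, kh, kw, N, H, W), dtype=dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, i, j] = xp[:, :, i:i + H, j:j + W].transpose(1, 0, 2, 3)
    cols2d = cols.reshape(C * kh * kw, N * H * W)
    w2d = w.data.reshape(Co, C * kh * kw).astype(dtype, copy=False)
    y = w2d @ cols2d                                          # (Co, N*H*W)
    if b is not None:
        y += b.data.astype(dtype, copy=False)[:, None]
    out = Tensor(np.ascontiguousarray(y.reshape(Co, N, H, W).transpose(1, 0, 2, 3)),
                 x.requires_grad or w.requires_grad or (b is not None and b.requires_grad),
                 (x, w) if b is None else (x, w, b))

    def bw(g):
        g2d = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(Co, N * H * W)
        if w.requires_grad:
            w._accum((g2d @ cols2d.T).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g2d.sum(axis=1))
        if x.requires_grad:
            dcols = (w2d.T @ g2d).reshape(C, kh, kw, N, H, W)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + H, j:j + W] += dcols[:, i, j].transpose(1, 0, 2, 3)
            x._accum(dxp[:, :, ph:ph + H, pw:pw + W])
    out._backward = bw
    return out


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float,
                mean: np.ndarray, var: np.ndarray,
                batch_stats: bool) -> Tensor:
    """Fused per-channel batch normalisation over axes (0, 2, 3).

    With ``batch_stats=True`` the statistics were computed from this
    batch and the backward pass accounts for their dependence on x;
    otherwise they are (running) constants.
    """
    inv = 1.0 / np.sqrt(var + np.asarray(eps, dtype=x.data.dtype))
    xhat = (x.data - mean) * inv
    out = Tensor(gamma.data * xhat + beta.data,
                 x.requires_grad or gamma.requires_grad or beta.requires_grad,
                 (x, gamma, beta))

    def bw(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3), keepdims=True))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3), keepdims=True))
        if x.requires_grad:
            if batch_stats:
                m = g.size // g.shape[1]
                gsum = g.sum(axis=(0, 2, 3), keepdims=True)
                gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
                x._accum((gamma.data * inv / m) * (m * g - gsum - xhat * gx))
            else:
                x._accum(g * gamma.data * inv)
    out._backward = bw
    return out


def maxpool2(x: Tensor) -> Tensor:
    """2×2 max pooling with stride 2; spatial dims must be even."""
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {H}x{W}")
    blocks = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    out = Tensor(blocks.max(axis=(3, 5)), x.requires_grad, (x,))

    def bw(g):
        if not x.requires_grad:
            return
        mx = out.data[:, :, :, None, :, None]
        mask = (blocks == mx)
        dx = mask * g[:, :, :, None, :, None]
        x._accum(dx.reshape(N, C, H, W))
    out._backward = bw
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2× spatial upsampling."""
    N, C, H, W = x.data.shape
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3),
                 x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))
    out._backward = bw
    return out
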
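"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the deblurring network needs: broadcasted
arithmetic, 2-D (grouped/depthwise) convolution via sliding windows,
pooling, nearest-neighbour upsampling, channel concatenation/slicing and
elementwise nonlinearities.  Float32 throughout; gradients accumulate in
the ``grad`` attribute after :meth:`Tensor.backward`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled"]

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


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
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

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff core --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        if not self.requires_grad:
            return
        grad = grad.astype(np.float32, copy=False)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __pow__(self, p: float):
        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / np.maximum(out_data, 1e-12))

        return Tensor._make(out_data, (self,), bw)

    def abs(self):
        def bw(g):
            self._accum(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0

        def bw(g):
            self._accum(g * np.where(mask, 1.0, slope).astype(np.float32))

        return Tensor._make(np.where(mask, self.data, slope * self.data), (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bw)

    def clamp(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), bw)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape

        def bw(g):
            self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), bw)

    def slice_channels(self, start: int, stop: int):
        """Return ``x[:, start:stop]`` (NCHW channel slice)."""
        c = self.shape[1]

        def bw(g):
            full = np.zeros(self.shape, dtype=np.float32)
            full[:, start:stop] = g
            self._accum(full)

        return Tensor._make(self.data[:, start:stop], (self,), bw)

    @staticmethod
    def cat(tensors, axis: int = 1):
        tensors = [Tensor._coerce(t) for t in tensors]
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

        return Tensor._make(
            np.concatenate([t.data for t in tensors], axis=axis), tensors, bw
        )

    # -- spatial ops (NCHW) ---------------------------------------------------
    def pad2d(self, p: int):
        """Zero-pad the last two axes by ``p`` on each side."""
        if p == 0:
            return self

        def bw(g):
            self._accum(g[..., p:-p, p:-p])

        return Tensor._make(
            np.pad(self.data, ((0, 0), (0, 0), (p, p), (p, p))), (self,), bw
        )

    def conv2d(self, weight: "Tensor", bias: "Tensor" = None, stride: int = 1,
               padding: int = 0):
        """Cross-correlation with ``weight`` of shape (OC, C, KH, KW)."""
        x = self.pad2d(padding) if padding else self
        xd = x.data
        oc, ic, kh, kw = weight.shape
        if ic != xd.shape[1]:
            raise ValueError(
                f"conv2d channel mismatch: input has {xd.shape[1]}, kernel expects {ic}"
            )
        if kh > xd.shape[2] or kw > xd.shape[3]:
            raise ValueError("conv2d kernel larger than (padded) input")
        win = np.lib.stride_tricks.sliding_window_view(xd, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]  # (N, C, OH, OW, KH, KW)
        out_data = np.tensordot(win, weight.data, axes=([1, 4, 5], [1, 2, 3]))
        out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, -1, 1, 1)
        n, _, oh, ow = out_data.shape
        parents = (x, weight) if bias is None else (x, weight, bias)

        def bw(g):
            if weight.requires_grad:
                dw = np.tensordot(win, g, axes=([0, 2, 3], [0, 2, 3]))
                weight._accum(dw.transpose(3, 0, 1, 2))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dx = np.zeros_like(xd)
                for i in range(kh):
                    for j in range(kw):
                        t = np.tensordot(g, weight.data[:, :, i, j], axes=([1], [0]))
                        dx[:, :, i : i + stride * oh : stride,
                           j : j + stride * ow : stride] += t.transpose(0, 3, 1, 2)
                x._accum(dx)

        return Tensor._make(out_data, parents, bw)

    def depthwise_conv2d(self, weight: "Tensor", bias: "Tensor" = None,
                         stride: int = 1, padding: int = 0):
        """Per-channel convolution; ``weight`` shape (C, KH, KW)."""
        x = self.pad2d(padding) if padding else self
        xd = x.data
        c, kh, kw = weight.shape
        if c != xd.shape[1]:
            raise ValueError("depthwise_conv2d channel mismatch")
        win = np.lib.stride_tricks.sliding_window_view(xd, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]
        out_data = np.einsum("nchwij,cij->nchw", win, weight.data, optimize=True)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, -1, 1, 1)
        n, _, oh, ow = out_data.shape
        parents = (x, weight) if bias is None else (x, weight, bias)

        def bw(g):
            if weight.requires_grad:
                weight._accum(np.einsum("nchwij,nchw->cij", win, g, optimize=True))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dx = np.zeros_like(xd)
                for i in range(kh):
                    for j in range(kw):
                        dx[:, :, i : i + stride * oh : stride,
                           j : j + stride * ow : stride] += (
                            g * weight.data[:, i, j].reshape(1, -1, 1, 1)
                        )
                x._accum(dx)

        return Tensor._make(out_data, parents, bw)

    def upsample_nearest2d(self, factor: int = 2):
        f = factor

        def bw(g):
            n, c, h, w = g.shape
            self._accum(
                g.reshape(n, c, h // f, f, w // f, f).sum(axis=(3, 5))
            )

        return Tensor._make(
            self.data.repeat(f, axis=2).repeat(f, axis=3), (self,), bw
        )

    def avg_pool2d(self, k: int = 2):
        n, c, h, w = self.shape
        if h % k or w % k:
            raise ValueError("avg_pool2d requires divisible spatial dims")
        out_data = self.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

        def bw(g):
            self._accum(g.repeat(k, axis=2).repeat(k, axis=3) / (k * k))

        return Tensor._make(out_data, (self,), bw)

    def global_avg_pool(self):
        return self.mean(axis=(2, 3), keepdims=True)
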
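"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the encoders, heads and training losses
need: broadcasting arithmetic, matmul, exp/log/pow, sigmoid, relu,
reductions, reshape/transpose/indexing/concatenation, 2-D convolution via
im2col and 2x2 max pooling.  Gradients are accumulated into ``.grad`` by
``Tensor.backward()`` over the topologically sorted graph.

Dtype policy: arrays keep the dtype they were created with (training code
uses float32 for speed; loss unit tests use float64 for tight oracles).
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
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic protocol -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):   # python scalars keep the dtype
            out_data = self.data + other

            def backward(g):
                return (g,)

            return Tensor._from_op(out_data, (self,), backward)
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out_data = self.data * other

            def backward(g):
                return (g * other,)

            return Tensor._from_op(out_data, (self,), backward)
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / (other.data**2), other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        if isinstance(other, (int, float)):
            out_data = other / self.data

            def backward(g):
                return (-g * out_data / self.data,)

            return Tensor._from_op(out_data, (self,), backward)
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor._from_op(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            return (g / self.data,)

        return Tensor._from_op(out_data, (self,), backward)

    def sqrt(self):
        return self**0.5

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            return (g * mask,)

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        x = self.data
        out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return Tensor._from_op(out_data, (self,), backward)

    def softplus(self):
        """log(1 + exp(x)), computed stably; gradient is sigmoid(x)."""
        x = self.data
        out_data = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))
        sig = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                       np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def backward(g):
            return (g * sig,)

        return Tensor._from_op(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through unclipped positions only."""
        mask = (self.data >= lo) & (self.data <= hi)
        out_data = np.clip(self.data, lo, hi)

        def backward(g):
            return (g * mask,)

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        expanded = self.data.max(axis=axis, keepdims=True)
        mask = self.data == expanded
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (mask * (g / counts),)

        return Tensor._from_op(out_data, (self,), backward)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        orig = self.shape

        def backward(g):
            return (g.reshape(orig),)

        return Tensor._from_op(out_data, (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(inv),)

        return Tensor._from_op(out_data, (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.shape
        dtype = self.dtype

        def backward(g):
            full = np.zeros(shape, dtype=dtype)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._from_op(out_data, (self,), backward)

    @staticmethod
    def concatenate(tensors, axis=0):
        tensors = [Tensor._wrap(t) for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            return tuple(np.split(g, splits, axis=axis))

        return Tensor._from_op(out_data, tuple(tensors), backward)

    @staticmethod
    def stack(tensors, axis=0):
        tensors = [Tensor._wrap(t) for t in tensors]
        out_data = np.stack([t.data for t in tensors], axis=axis)

        def backward(g):
            parts = np.split(g, len(tensors), axis=axis)
            return tuple(np.squeeze(p, axis=axis) for p in parts)

        return Tensor._from_op(out_data, tuple(tensors), backward)

    # -- backward pass --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                key = id(p)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
        # leaves reached directly (self may be a leaf)
        if self._backward is None and self._parents == ():
            self.grad = grads.get(id(self), self.grad)


# -- convolution / pooling (dedicated ops for speed) ---------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (x.shape[2] - kh) // stride + 1
    ow = (x.shape[3] - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]  # n,c,oh,ow,kh,kw
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw)
    return cols, oh, ow


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           pad: int = 1) -> Tensor:
    """2-D convolution, NCHW layout, weight (O, C, kh, kw)."""
    xw = Tensor._wrap(x)
    n, c, h, w = xw.shape
    o, cc, kh, kw = weight.shape
    if cc != c:
        raise ValueError(f"channel mismatch: input {c}, weight {cc}")
    cols, oh, ow = _im2col(xw.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(o, -1)
    out = cols @ wmat.T  # n, oh*ow, o
    if bias is not None:
        out = out + bias.data
    out = out.transpose(0, 2, 1).reshape(n, o, oh, ow)
    cols_saved = cols

    def backward(g):
        gmat = np.ascontiguousarray(
            g.reshape(n, o, oh * ow).transpose(0, 2, 1))  # n, ohw, o
        gflat = gmat.reshape(-1, o)
        gw = (gflat.T @ cols_saved.reshape(-1, wmat.shape[1])).reshape(weight.shape)
        gb = gflat.sum(axis=0) if bias is not None else None
        gcols = gmat @ wmat  # n, ohw, c*kh*kw
        # col2im scatter
        gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=xw.dtype)
        gcols = gcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                    gcols[:, :, :, :, i, j]
        if pad:
            gx = gx[:, :, pad:-pad, pad:-pad]
        if bias is not None:
            return gx, gw, gb
        return gx, gw

    parents = (xw, weight) if bias is None else (xw, weight, bias)
    return Tensor._from_op(out, parents, backward)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused training-mode batch normalization over (N, C, H, W).

    Returns (out, batch_mean, batch_var) with the closed-form backward.
    """
    xw = Tensor._wrap(x)
    data = xw.data
    n, c, h, w = data.shape
    m = n * h * w
    mean = data.mean(axis=(0, 2, 3))
    var = data.var(axis=(0, 2, 3))
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (data - mean.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
    out = xhat * gamma.data.reshape(1, c, 1, 1) + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        dbeta = g.sum(axis=(0, 2, 3))
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dxhat = g * gamma.data.reshape(1, c, 1, 1)
        s1 = dxhat.sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
        dx = (inv_std.reshape(1, c, 1, 1) / m) * (m * dxhat - s1 - xhat * s2)
        return dx.astype(data.dtype), dgamma.astype(gamma.dtype), \
            dbeta.astype(beta.dtype)

    out_t = Tensor._from_op(out.astype(data.dtype), (xw, gamma, beta), backward)
    return out_t, mean, var


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    xw = Tensor._wrap(x)
    n, c, h, w = xw.shape
    oh, ow = h // k, w // k
    view = xw.data[:, :, :oh * k, :ow * k].reshape(n, c, oh, k, ow, k)
    flat = view.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, k * k)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(n, c, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5)
        gx = gx.reshape(n, c, oh * k, ow * k)
        if (oh * k, ow * k) != (h, w):
            full = np.zeros((n, c, h, w), dtype=xw.dtype)
            full[:, :, :oh * k, :ow * k] = gx
            gx = full
        return (gx,)

    return Tensor._from_op(out, (xw,), backward)
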
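"""A small reverse-mode automatic-differentiation engine on numpy arrays.

This is the package's own CPU engine for building and training the keypoint
network: a taped :class:`Tensor`, the handful of differentiable operations the
hourglass architecture needs (2-D convolution, pooling, upsampling, attention
gates, a spatial soft-argmax), thin ``Module``/layer containers and an SGD
optimizer with momentum and weight decay.

Convolutions are evaluated as a sum of BLAS matrix products over kernel
offsets (one ``tensordot`` per tap), which is the fastest pure-numpy layout
for the small feature maps used here. Parameters default to float32; the
engine is dtype-preserving, so float64 tensors can be used for gradient
checking.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "add",
    "mul",
    "sub",
    "div",
    "relu",
    "sigmoid",
    "exp",
    "absolute",
    "arctan2",
    "sqrt",
    "getitem",
    "concat",
    "reduce_sum",
    "reduce_mean",
    "reduce_max",
    "conv2d",
    "maxpool2x2",
    "upsample2x",
    "soft_argmax2d",
    "Module",
    "Conv2d",
    "SGD",
    "he_init",
    "count_parameters",
]


class Tensor:
    """An n-d array node in the backward tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: Tuple["Tensor", ...] = (), _bwd: Optional[Callable] = None):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._bwd = _bwd

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Reverse-mode sweep seeding ``grad`` (ones for a scalar) at self."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()
        stack: List[Tuple[Tensor, bool]] = [(self, False)]
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
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._bwd is not None and node.grad is not None:
                node._bwd(node.grad)

    # operator sugar (numpy-array or scalar rhs is wrapped as a constant)
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __neg__(self):
        return mul(self, _wrap(np.asarray(-1.0, dtype=self.data.dtype)))

    def __getitem__(self, idx):
        return getitem(self, idx)


def tensor(data, requires_grad: bool = False, dtype=np.float32) -> Tensor:
    return Tensor(np.asarray(data, dtype=dtype), requires_grad=requires_grad)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, _parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._bwd = bwd
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data, _parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.data.shape))

    out._bwd = bwd
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, _parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._bwd = bwd
    return out


def div(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data / b.data, _parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    out._bwd = bwd
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, _parents=(a,))
    out._bwd = lambda g: a._accumulate(g * mask)
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, _parents=(a,))
    out._bwd = lambda g: a._accumulate(g * s * (1.0 - s))
    return out


def exp(a: Tensor) -> Tensor:
    e = np.exp(a.data)
    out = Tensor(e, _parents=(a,))
    out._bwd = lambda g: a._accumulate(g * e)
    return out


def sqrt(a: Tensor) -> Tensor:
    r = np.sqrt(a.data)
    out = Tensor(r, _parents=(a,))
    out._bwd = lambda g: a._accumulate(g * 0.5 / np.maximum(r, np.finfo(r.dtype).tiny))
    return out


def absolute(a: Tensor) -> Tensor:
    out = Tensor(np.abs(a.data), _parents=(a,))
    out._bwd = lambda g: a._accumulate(g * np.sign(a.data))
    return out


def arctan2(y: Tensor, x: Tensor) -> Tensor:
    out = Tensor(np.arctan2(y.data, x.data), _parents=(y, x))

    def bwd(g):
        denom = y.data * y.data + x.data * x.data
        denom = np.maximum(denom, np.finfo(out.data.dtype).tiny)
        if y.requires_grad:
            y._accumulate(_unbroadcast(g * x.data / denom, y.data.shape))
        if x.requires_grad:
            x._accumulate(_unbroadcast(-g * y.data / denom, x.data.shape))

    out._bwd = bwd
    return out


def getitem(a: Tensor, idx) -> Tensor:
    out = Tensor(a.data[idx], _parents=(a,))

    def bwd(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accumulate(full)

    out._bwd = bwd
    return out


def concat(parts: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis), _parents=tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                p._accumulate(g[tuple(sl)])

    out._bwd = bwd
    return out


def reduce_sum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), _parents=(a,))

    def bwd(g):
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, ax)
        a._accumulate(np.broadcast_to(g, a.data.shape).astype(a.data.dtype))

    out._bwd = bwd
    return out


def reduce_mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    s = reduce_sum(a, axis=axis, keepdims=keepdims)
    return mul(s, _wrap(np.asarray(1.0 / n, dtype=a.data.dtype)))


def reduce_max(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    m = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == m)
    mask = mask / mask.sum(axis=axis, keepdims=True)  # split ties evenly
    out_data = m if keepdims else np.squeeze(m, axis=axis)
    out = Tensor(out_data, _parents=(a,))

    def bwd(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate((g * mask).astype(a.data.dtype))

    out._bwd = bwd
    return out


# ---------------------------------------------------------------------------
# spatial ops


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    Evaluated as one im2col matrix product (a strided view reshaped into a
    ``(Ci*kh*kw, N*Ho*Wo)`` matrix hitting BLAS once per direction).
    """
    N, Ci, H, W = x.data.shape
    Co, Ci2, kh, kw = w.data.shape
    if Ci != Ci2:
        raise ValueError(f"channel mismatch: input {Ci}, kernel {Ci2}")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // s + 1
    Wo = (Wp - kw) // s + 1
    sN, sC, sH, sW = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(Ci, kh, kw, N, Ho, Wo),
        strides=(sC, sH, sW, sN, sH * s, sW * s))
    cols = np.ascontiguousarray(view.reshape(Ci * kh * kw, N * Ho * Wo))
    w2 = w.data.reshape(Co, Ci * kh * kw)
    out_data = np.ascontiguousarray(
        (w2 @ cols).reshape(Co, N, Ho, Wo).transpose(1, 0, 2, 3))
    if b is not None:
        out_data += b.data.reshape(1, Co, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _parents=parents)

    def bwd(g):
        g2 = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(Co, N * Ho * Wo)
        if w.requires_grad:
            w._accumulate((g2 @ cols.T).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g2.sum(axis=1))
        if x.requires_grad:
            dcols = (w2.T @ g2).reshape(Ci, kh, kw, N, Ho, Wo)
            dxp = np.zeros((N, Ci, Hp, Wp), dtype=x.data.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + s * (Ho - 1) + 1:s,
                        j:j + s * (Wo - 1) + 1:s] += dcols[:, i, j].transpose(1, 0, 2, 3)
            x._accumulate(dxp[:, :, p:Hp - p, p:Wp - p] if p else dxp)

    out._bwd = bwd
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {H}x{W}")
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    out_data = xr.max(axis=(3, 5))
    mask = xr == out_data[:, :, :, None, :, None]
    mask = mask / mask.sum(axis=(3, 5), keepdims=True)
    out = Tensor(out_data, _parents=(x,))

    def bwd(g):
        gx = (g[:, :, :, None, :, None] * mask).reshape(N, C, H, W)
        x._accumulate(gx.astype(x.data.dtype))

    out._bwd = bwd
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), _parents=(x,))

    def bwd(g):
        N, C, H2, W2 = g.shape
        x._accumulate(g.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)))

    out._bwd = bwd
    return out


def soft_argmax2d(scores: Tensor) -> Tensor:
    """Integral regression: expected pixel-center coordinate under a softmax.

    Input ``(N, K, H, W)`` raw scores; output ``(N, K, 2)`` continuous
    ``(x, y)`` coordinates in grid units, strictly inside ``[0, W-1] x
    [0, H-1]`` because they are convex combinations of pixel centers.
    """
    d = scores.data
    if np.isnan(d).all():
        raise FloatingPointError("all-NaN score grid")
    N, K, H, W = d.shape
    flat = d.reshape(N, K, H * W)
    m = flat.max(axis=2, keepdims=True)
    e = np.exp(flat - m)
    p = e / e.sum(axis=2, keepdims=True)  # (N,K,HW)
    gy, gx = np.mgrid[0:H, 0:W]
    gx = gx.reshape(-1).astype(d.dtype)
    gy = gy.reshape(-1).astype(d.dtype)
    xs = p @ gx
    ys = p @ gy
    out = Tensor(np.stack([xs, ys], axis=2), _parents=(scores,))

    def bwd(g):
        # dL/dp_i = gx_i * dx + gy_i * dy ; softmax backward
        dp = g[:, :, 0:1] * gx[None, None, :] + g[:, :, 1:2] * gy[None, None, :]
        ds = p * (dp - (p * dp).sum(axis=2, keepdims=True))
        scores._accumulate(ds.reshape(N, K, H, W).astype(d.dtype))

    out._bwd = bwd
    return out


# ---------------------------------------------------------------------------
# modules


def he_init(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int,
            dtype=np.float32) -> np.ndarray:
    """He/Kaiming fan-in normal initialization for ReLU networks."""
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(dtype)


class Module:
    """Base container; collects parameters from attributes recursively."""

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        seen = set()

        def visit(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)

        visit(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> List[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        params = self.parameters()
        arrays = list(arrays)
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Convolution layer with He-initialized weights and zero bias."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 padding: Optional[int] = None, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = cin * kernel * kernel
        self.w = Tensor(he_init(rng, (cout, cin, kernel, kernel), fan_in), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class SGD:
    """Stochastic gradient descent with classical momentum and weight decay."""

    def __init__(self, params: Sequence[Tensor], lr: float,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def count_parameters(m: Module) -> int:
    return int(sum(p.data.size for p in m.parameters()))
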
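"""Minimal reverse-mode autodiff over numpy arrays.

The package trains and evaluates 3D attention networks on CPU; this module
supplies the tensor/layer machinery: a taped :class:`Tensor`, the handful of
differentiable ops the architecture needs, ``Module``/``Parameter``
containers, and a multiply-accumulate (MAC) counting context used by the
complexity analysis.  All network math is float32; gradients are float32.
"""
from __future__ import annotations

import contextlib
import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor", "Parameter", "Module", "ModuleList", "Linear", "Conv3d",
    "LayerNorm", "InstanceNorm3d", "no_grad", "count_macs", "concat",
    "softmax", "log_softmax", "gelu", "leaky_relu", "gather_rows",
]

_grad_enabled = [True]
_mac_counter = [None]


@contextlib.contextmanager
def no_grad():
    """Disable taping; forward results carry no graph."""
    _grad_enabled.append(False)
    try:
        yield
    finally:
        _grad_enabled.pop()


class MacCount:
    """Accumulator for multiply-accumulate operations of Linear/Conv3d."""

    def __init__(self) -> None:
        self.total = 0

    def add(self, n: int) -> None:
        self.total += int(n)


@contextlib.contextmanager
def count_macs():
    """Count MACs executed by Linear and Conv3d layers inside the block.

    Mirrors the hook-based complexity counters common in vision frameworks:
    only projection layers (dense and convolutional) are counted; attention
    score products, normalisations and activations are not.
    """
    c = MacCount()
    _mac_counter.append(c)
    try:
        yield c
    finally:
        _mac_counter.pop()


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
    """An ndarray with an optional backward tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _bw=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._bw = _bw

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, bw) -> "Tensor":
        if _grad_enabled[-1] and any(p.requires_grad for p in parents):
            return Tensor(data, True, tuple(parents), bw)
        return Tensor(data)

    # -- basic info -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd -------------------------------------------------------------
    def backward(self, grad=None) -> None:
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
            if t._bw is not None:
                t._bw(t.grad)
            t._parents = ()
            t._bw = None

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float32), self.data.shape)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None else g
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        o = self._wrap(other)
        out_data = self.data + o.data

        def bw(g):
            self._accum(g)
            o._accum(g)
        return self._make(out_data, (self, o), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)
        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        o = self._wrap(other)
        out_data = self.data * o.data

        def bw(g):
            self._accum(g * o.data)
            o._accum(g * self.data)
        return self._make(out_data, (self, o), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._wrap(other)
        return self * o.pow(-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self.pow(-1.0)

    def pow(self, p: float):
        out_data = self.data ** p

        def bw(g):
            self._accum(g * p * self.data ** (p - 1.0))
        return self._make(out_data, (self,), bw)

    def sqrt(self):
        return self.pow(0.5)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)
        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)
        return self._make(np.log(self.data), (self,), bw)

    def __matmul__(self, other):
        o = self._wrap(other)
        out_data = self.data @ o.data

        def bw(g):
            self._accum(g @ np.swapaxes(o.data, -1, -2))
            o._accum(np.swapaxes(self.data, -1, -2) @ g)
        return self._make(out_data, (self, o), bw)

    # -- shaping --------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))
        return self._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))

        def bw(g):
            self._accum(g.transpose(inv))
        return self._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, key):
        def bw(g):
            full = np.zeros_like(self.data)
            full[key] += g
            self._accum(full)
        return self._make(self.data[key], (self,), bw)

    def pad(self, pad_width):
        pw = tuple(tuple(p) for p in pad_width)
        sl = tuple(slice(a, a + s) for (a, _), s in zip(pw, self.data.shape))

        def bw(g):
            self._accum(g[sl])
        return self._make(np.pad(self.data, pw), (self,), bw)

    def roll(self, shift: Sequence[int], axis: Sequence[int]):
        shift, axis = tuple(shift), tuple(axis)

        def bw(g):
            self._accum(np.roll(g, tuple(-s for s in shift), axis))
        return self._make(np.roll(self.data, shift, axis), (self,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape))
        return self._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])
    return Tensor._make(out_data, tuple(tensors), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        x._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))
    return Tensor._make(s, (x,), bw)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    ls = z - np.log(np.exp(z).sum(axis=axis, keepdims=True))

    def bw(g):
        x._accum(g - np.exp(ls) * g.sum(axis=axis, keepdims=True))
    return Tensor._make(ls, (x,), bw)


_SQRT2 = math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _erf(x: np.ndarray) -> np.ndarray:
    from scipy.special import erf
    return erf(x)


def gelu(x: Tensor) -> Tensor:
    xd = x.data
    out_data = 0.5 * xd * (1.0 + _erf(xd / _SQRT2))

    def bw(g):
        d = 0.5 * (1.0 + _erf(xd / _SQRT2)) + xd * _INV_SQRT2PI * np.exp(-0.5 * xd * xd)
        x._accum(g * d)
    return Tensor._make(out_data.astype(np.float32), (x,), bw)


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    mask = x.data >= 0
    out_data = np.where(mask, x.data, slope * x.data)

    def bw(g):
        x._accum(np.where(mask, g, slope * g))
    return Tensor._make(out_data, (x,), bw)


def gather_rows(table: Tensor, idx: np.ndarray) -> Tensor:
    """table[idx] along axis 0 with scatter-add backward."""
    idx = np.asarray(idx)

    def bw(g):
        full = np.zeros_like(table.data)
        np.add.at(full, idx, g)
        table._accum(full)
    return Tensor._make(table.data[idx], (table,), bw)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------
class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container with recursive parameter discovery (torch-like, minimal)."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(key + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self) -> Iterable[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)[:3]} "
                           f"extra={sorted(extra)[:3]}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        self.mods = list(mods)

    def __iter__(self):
        return iter(self.mods)

    def __len__(self):
        return len(self.mods)

    def __getitem__(self, i):
        return self.mods[i]

    def append(self, m):
        self.mods.append(m)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated normal init (+-2 std), the transformer convention."""
    x = rng.standard_normal(shape) * std
    return np.clip(x, -2 * std, 2 * std).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(trunc_normal(rng, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        c = _mac_counter[-1]
        if c is not None:
            rows = int(np.prod(x.shape[:-1]))
            c.add(rows * self.in_features * self.out_features)
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv3d(Module):
    """3D convolution, stride 1, zero 'same' padding for odd kernels."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = False, padding: int | None = None):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = in_channels * kernel_size ** 3
        bound = math.sqrt(2.0 / fan_in)  # He init for LeakyReLU stacks
        w = rng.standard_normal(
            (out_channels, in_channels) + (kernel_size,) * 3) * bound
        self.weight = Parameter(w.astype(np.float32))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = _conv3d(x, self.weight, self.kernel_size, self.padding)
        c = _mac_counter[-1]
        if c is not None:
            c.add(int(np.prod(out.shape)) // self.out_channels *
                  self.out_channels * self.in_channels * self.kernel_size ** 3)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1, 1, 1)
        return out


_CONV_CHUNK_VOX = 8192  # target voxels per im2col chunk, bounds peak memory


def _conv3d(x: Tensor, weight: Parameter, k: int, pad: int) -> Tensor:
    """stride-1 conv via im2col, chunked along the depth axis; x: (B, Cin, D, H, W)."""
    B, Cin, D, H, W = x.shape
    Cout = weight.shape[0]
    Do, Ho, Wo = D + 2 * pad - k + 1, H + 2 * pad - k + 1, W + 2 * pad - k + 1
    xp = np.pad(x.data, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    flat = view.transpose(0, 2, 3, 4, 1, 5, 6, 7)  # (B,Do,Ho,Wo,Cin,k,k,k) view
    wmat = weight.data.reshape(Cout, Cin * k ** 3).T  # (Cin*k^3, Cout)
    step = max(1, _CONV_CHUNK_VOX // (Ho * Wo))
    out = np.empty((B, Do, Ho, Wo, Cout), dtype=np.float32)
    for a in range(0, Do, step):
        b = min(a + step, Do)
        col = np.ascontiguousarray(flat[:, a:b]).reshape(
            B, (b - a) * Ho * Wo, Cin * k ** 3)
        out[:, a:b] = (col @ wmat).reshape(B, b - a, Ho, Wo, Cout)
    out_data = np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))

    def bw(g):
        # g: (B, Cout, Do, Ho, Wo)
        gmove = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1))  # (B,Do,Ho,Wo,Cout)
        dw = np.zeros((Cin * k ** 3, Cout), dtype=np.float32)
        dxp = np.zeros_like(xp)
        for a in range(0, Do, step):
            b = min(a + step, Do)
            n = (b - a) * Ho * Wo
            col = np.ascontiguousarray(flat[:, a:b]).reshape(B, n, Cin * k ** 3)
            gc = gmove[:, a:b].reshape(B, n, Cout)
            dw += np.einsum("bnc,bno->co", col, gc, optimize=True)
            dcol = (gc @ wmat.T).reshape(B, b - a, Ho, Wo, Cin, k, k, k)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        dxp[:, :, a + i:b + i, j:j + Ho, l:l + Wo] += \
                            dcol[:, :, :, :, :, i, j, l].transpose(0, 4, 1, 2, 3)
        weight._accum(dw.T.reshape(weight.data.shape))
        if pad:
            x._accum(dxp[:, :, pad:-pad, pad:-pad, pad:-pad])
        else:
            x._accum(dxp)
    return Tensor._make(out_data, (x, weight), bw)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.dim = dim
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps).pow(-0.5) * self.weight + self.bias


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalisation over spatial dims; affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.channels = channels
        self.eps = eps
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:  # (B, C, D, H, W)
        ax = (2, 3, 4)
        mu = x.mean(axis=ax, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=ax, keepdims=True)
        y = xc * (var + self.eps).pow(-0.5)
        return y * self.weight.reshape(1, -1, 1, 1, 1) + self.bias.reshape(1, -1, 1, 1, 1)
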
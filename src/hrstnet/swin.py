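"""3D windowed and shifted-window multi-head self-attention.

Feature maps live on a 3D token grid: a volume of shape (D, H, W) embedded at
patch stride P becomes d*h*w tokens of width C, stored row-major in (d, h, w)
order.  Attention is restricted to non-overlapping ``window_size`` blocks of
the grid (W-MSA); every second layer cyclically shifts the grid by half a
window first (SW-MSA) so information can cross window borders, with an
additive mask blocking token pairs that are not spatially contiguous after
the shift.  Grids that do not divide the window are zero-padded and the
padded tokens are masked out of the softmax.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._tensor import (
    Linear, LayerNorm, Module, ModuleList, Parameter, Tensor, gelu,
    gather_rows, softmax, trunc_normal,
)

MASK_NEG = -1e4  # additive attention mask value for blocked pairs

Triple = tuple[int, int, int]


def _triple(v) -> Triple:
    if isinstance(v, int):
        return (v, v, v)
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected an int or length-3 triple, got {v!r}")
    return t


@dataclass
class TokenGrid:
    """A 3D feature map flattened to tokens.

    ``values`` has shape (B, d*h*w, C); tokens are ordered row-major over
    (d, h, w).
    """

    values: Tensor
    grid_dims: Triple

    def __post_init__(self):
        self.grid_dims = _triple(self.grid_dims)
        d, h, w = self.grid_dims
        if self.values.ndim != 3:
            raise ValueError("TokenGrid values must be (batch, tokens, channels)")
        if self.values.shape[1] != d * h * w:
            raise ValueError(
                f"token count {self.values.shape[1]} != d*h*w = {d * h * w}")

    @property
    def embed_dim(self) -> int:
        return self.values.shape[-1]

    @property
    def batch(self) -> int:
        return self.values.shape[0]


@dataclass
class SwinBlockConfig:
    """Hyperparameters of one shifted-window transformer block.

    ``depth`` counts attention layers; even layers use unshifted windows,
    odd layers shift by ``shift_size`` (default half a window).  ``depth=2``
    is one W-MSA/SW-MSA pair.
    """

    depth: int = 2
    num_heads: int = 3
    window_size: Triple = (7, 7, 7)
    shift_size: Triple | None = None
    mlp_ratio: float = 4.0
    qkv_bias: bool = True

    def __post_init__(self):
        self.window_size = _triple(self.window_size)
        if any(w <= 0 for w in self.window_size):
            raise ValueError(f"window_size must be positive, got {self.window_size}")
        if self.shift_size is None:
            self.shift_size = tuple(w // 2 for w in self.window_size)
        else:
            self.shift_size = _triple(self.shift_size)
        for s, w in zip(self.shift_size, self.window_size):
            if not 0 <= s < w:
                raise ValueError(f"need 0 <= shift < window, got {self.shift_size} "
                                 f"vs {self.window_size}")
        if self.num_heads <= 0 or self.depth <= 0:
            raise ValueError("depth and num_heads must be positive")


# ---------------------------------------------------------------------------
# window bookkeeping
# ---------------------------------------------------------------------------
def _pad_amounts(grid_dims: Triple, window_size: Triple) -> Triple:
    return tuple((-g) % w for g, w in zip(grid_dims, window_size))


def window_partition(x: TokenGrid, window_size) -> tuple[Tensor, np.ndarray]:
    """Split a token grid into non-overlapping windows.

    Grids not divisible by the window are zero-padded on the high side.
    Returns ``(windows, valid)`` where windows has shape
    (B, n_windows, wd*wh*ww, C) and ``valid`` flags the non-padded positions
    per window.
    """
    window_size = _triple(window_size)
    if any(w <= 0 for w in window_size):
        raise ValueError(f"window_size must be positive, got {window_size}")
    d, h, w = x.grid_dims
    wd, wh, ww = window_size
    pd, ph, pw = _pad_amounts(x.grid_dims, window_size)
    B, _, C = x.values.shape
    v = x.values.reshape(B, d, h, w, C)
    if pd or ph or pw:
        v = v.pad(((0, 0), (0, pd), (0, ph), (0, pw), (0, 0)))
    D, H, W = d + pd, h + ph, w + pw
    v = v.reshape(B, D // wd, wd, H // wh, wh, W // ww, ww, C)
    v = v.transpose(0, 1, 3, 5, 2, 4, 6, 7)
    nw = (D // wd) * (H // wh) * (W // ww)
    windows = v.reshape(B, nw, wd * wh * ww, C)

    ones = np.zeros((D, H, W), dtype=bool)
    ones[:d, :h, :w] = True
    valid = ones.reshape(D // wd, wd, H // wh, wh, W // ww, ww)
    valid = valid.transpose(0, 2, 4, 1, 3, 5).reshape(nw, wd * wh * ww)
    return windows, valid


def window_reverse(windows: Tensor, grid_dims, window_size) -> TokenGrid:
    """Inverse of :func:`window_partition`; crops any padding."""
    grid_dims = _triple(grid_dims)
    window_size = _triple(window_size)
    d, h, w = grid_dims
    wd, wh, ww = window_size
    pd, ph, pw = _pad_amounts(grid_dims, window_size)
    D, H, W = d + pd, h + ph, w + pw
    B, nw, wt, C = windows.shape
    if nw != (D // wd) * (H // wh) * (W // ww) or wt != wd * wh * ww:
        raise ValueError("window layout inconsistent with grid_dims/window_size")
    v = windows.reshape(B, D // wd, H // wh, W // ww, wd, wh, ww, C)
    v = v.transpose(0, 1, 4, 2, 5, 3, 6, 7).reshape(B, D, H, W, C)
    if pd or ph or pw:
        v = v[:, :d, :h, :w, :]
    return TokenGrid(v.reshape(B, d * h * w, C), grid_dims)


def cyclic_shift(x: TokenGrid, shift) -> TokenGrid:
    """Roll the grid by ``-shift`` along each spatial axis."""
    shift = _triple(shift)
    d, h, w = x.grid_dims
    B, _, C = x.values.shape
    v = x.values.reshape(B, d, h, w, C).roll(
        tuple(-s for s in shift), (1, 2, 3)).reshape(B, d * h * w, C)
    return TokenGrid(v, x.grid_dims)


def _axis_regions(length: int, window: int, shift: int) -> np.ndarray:
    """Region ids along one padded axis for the shift mask."""
    ids = np.zeros(length, dtype=np.int64)
    if shift:
        ids[length - window:length - shift] = 1
        ids[length - shift:] = 2
    return ids


def compute_attention_mask(grid_dims, window_size, shift_size) -> np.ndarray:
    """Additive per-window mask of shape (n_windows, wt, wt).

    Token pairs from non-contiguous regions after the cyclic shift, and any
    pair involving a zero-padded position, get ``MASK_NEG``; valid contiguous
    pairs get 0.  ``grid_dims`` are the unpadded dims; padding to window
    multiples is handled here.
    """
    grid_dims = _triple(grid_dims)
    window_size = _triple(window_size)
    shift_size = _triple(shift_size)
    d, h, w = grid_dims
    pd, ph, pw = _pad_amounts(grid_dims, window_size)
    D, H, W = d + pd, h + ph, w + pw
    ad = _axis_regions(D, window_size[0], shift_size[0])
    ah = _axis_regions(H, window_size[1], shift_size[1])
    aw = _axis_regions(W, window_size[2], shift_size[2])
    lab = (ad[:, None, None] * 3 + ah[None, :, None]) * 3 + aw[None, None, :]
    lab[d:, :, :] = -1
    lab[:, h:, :] = -1
    lab[:, :, w:] = -1
    lab = np.roll(lab, tuple(-s for s in shift_size), (0, 1, 2))
    wd, wh, ww = window_size
    lab = lab.reshape(D // wd, wd, H // wh, wh, W // ww, ww)
    lab = lab.transpose(0, 2, 4, 1, 3, 5).reshape(-1, wd * wh * ww)
    same = lab[:, :, None] == lab[:, None, :]
    return np.where(same, 0.0, MASK_NEG).astype(np.float32)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------
class WindowAttention(Module):
    """Multi-head self-attention within windows, with a learned 3D relative
    position bias table of shape ((2wd-1)(2wh-1)(2ww-1), heads)."""

    def __init__(self, dim: int, num_heads: int, window_size,
                 rng: np.random.Generator, qkv_bias: bool = True):
        window_size = _triple(window_size)
        if dim % num_heads:
            raise ValueError(f"embed dim {dim} not divisible by {num_heads} heads")
        self.dim = dim
        self.num_heads = num_heads
        self.window_size = window_size
        self.head_dim = dim // num_heads
        self.scale = self.head_dim ** -0.5
        self.qkv = Linear(dim, 3 * dim, rng, bias=qkv_bias)
        self.proj = Linear(dim, dim, rng)
        wd, wh, ww = window_size
        table = (2 * wd - 1) * (2 * wh - 1) * (2 * ww - 1)
        self.relative_position_bias_table = Parameter(
            trunc_normal(rng, (table, num_heads)))
        self._rel_index = self._relative_index(window_size)

    @staticmethod
    def _relative_index(window_size: Triple) -> np.ndarray:
        wd, wh, ww = window_size
        coords = np.stack(np.meshgrid(
            np.arange(wd), np.arange(wh), np.arange(ww), indexing="ij"), axis=-1)
        coords = coords.reshape(-1, 3)
        rel = coords[:, None, :] - coords[None, :, :]
        rel += np.array([wd - 1, wh - 1, ww - 1])
        idx = (rel[..., 0] * (2 * wh - 1) + rel[..., 1]) * (2 * ww - 1) + rel[..., 2]
        return idx.reshape(-1)

    def forward(self, windows: Tensor, mask: np.ndarray | None = None) -> Tensor:
        B, nw, wt, C = windows.shape
        H, hd = self.num_heads, self.head_dim
        qkv = self.qkv(windows).reshape(B, nw, wt, 3, H, hd)
        qkv = qkv.transpose(3, 0, 1, 4, 2, 5)  # (3, B, nw, H, wt, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = (q * self.scale) @ k.transpose(0, 1, 2, 4, 3)  # (B, nw, H, wt, wt)
        bias = gather_rows(self.relative_position_bias_table, self._rel_index)
        bias = bias.reshape(wt, wt, H).transpose(2, 0, 1).reshape(1, 1, H, wt, wt)
        attn = attn + bias
        if mask is not None:
            attn = attn + Tensor(mask.reshape(1, nw, 1, wt, wt))
        attn = softmax(attn, axis=-1)
        out = attn @ v  # (B, nw, H, wt, hd)
        out = out.transpose(0, 1, 3, 2, 4).reshape(B, nw, wt, C)
        return self.proj(out)


def windowed_attention(x: TokenGrid, attn: WindowAttention,
                       shift=(0, 0, 0), mask="auto") -> TokenGrid:
    """Apply window attention over a token grid (pad -> shift -> partition ->
    attend -> reverse -> unshift -> crop).  Shape preserving.

    ``mask="auto"`` derives the shift/padding mask from the geometry;
    ``None`` applies no mask.
    """
    shift = _triple(shift)
    window = attn.window_size
    pads = _pad_amounts(x.grid_dims, window)
    padded_dims = tuple(g + p for g, p in zip(x.grid_dims, pads))
    if isinstance(mask, str) and mask == "auto":
        mask = compute_attention_mask(x.grid_dims, window, shift)
        if not mask.any():
            mask = None
    d, h, w = x.grid_dims
    B, _, C = x.values.shape
    v = x.values.reshape(B, d, h, w, C)
    if any(pads):
        v = v.pad(((0, 0), (0, pads[0]), (0, pads[1]), (0, pads[2]), (0, 0)))
    g = TokenGrid(v.reshape(B, -1, C), padded_dims)
    if any(shift):
        g = cyclic_shift(g, shift)
    windows, _ = window_partition(g, window)
    out = attn(windows, mask)
    g = window_reverse(out, padded_dims, window)
    if any(shift):
        g = cyclic_shift(g, tuple(-s for s in shift))
    if any(pads):
        vv = g.values.reshape(B, *padded_dims, C)[:, :d, :h, :w, :]
        g = TokenGrid(vv.reshape(B, d * h * w, C), x.grid_dims)
    else:
        g = TokenGrid(g.values, x.grid_dims)
    return g


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class SwinLayer(Module):
    """One pre-norm attention layer: x + attn(LN(x)), x + MLP(LN(x))."""

    def __init__(self, dim: int, cfg: SwinBlockConfig, shift: Triple,
                 rng: np.random.Generator):
        self.shift = shift
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, cfg.num_heads, cfg.window_size, rng,
                                    cfg.qkv_bias)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * cfg.mlp_ratio), rng)
        self._mask_cache: dict[Triple, np.ndarray | None] = {}

    def forward(self, x: TokenGrid) -> TokenGrid:
        key = x.grid_dims
        if key not in self._mask_cache:
            m = compute_attention_mask(key, self.attn.window_size, self.shift)
            self._mask_cache[key] = m if m.any() else None
        mask = self._mask_cache[key]
        a = windowed_attention(TokenGrid(self.norm1(x.values), x.grid_dims),
                               self.attn, self.shift, mask)
        v = x.values + a.values
        v = v + self.mlp(self.norm2(v))
        return TokenGrid(v, x.grid_dims)


class SwinBlock(Module):
    """``depth`` cascaded layers alternating W-MSA (shift 0) and SW-MSA."""

    def __init__(self, dim: int, cfg: SwinBlockConfig, rng: np.random.Generator):
        if dim % cfg.num_heads:
            raise ValueError(f"embed dim {dim} not divisible by {cfg.num_heads} heads")
        self.dim = dim
        self.cfg = cfg
        zero = (0, 0, 0)
        self.layers = ModuleList([
            SwinLayer(dim, cfg, zero if i % 2 == 0 else cfg.shift_size, rng)
            for i in range(cfg.depth)])

    def forward(self, x: TokenGrid) -> TokenGrid:
        for layer in self.layers:
            x = layer(x)
        return x


def swin_block_forward(x: TokenGrid, block: SwinBlock) -> TokenGrid:
    """Functional alias for :meth:`SwinBlock.forward`."""
    return block(x)
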
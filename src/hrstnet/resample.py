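"""Resolution changes on token grids: patch embedding, merging, expanding.

Patch embedding projects each non-overlapping P^3 patch of a K-channel
volume to a C-vector, giving floor(D/P) x floor(H/P) x floor(W/P) tokens.
Patch merging concatenates 2x2x2 neighbouring tokens (8C) and projects to
2C, halving each grid axis.  Patch expanding is the inverse-shape move:
project C -> 2C, then scatter each token into a 2x2x2 block of sub-tokens of
width C/4, doubling each axis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import LayerNorm, Linear, Module, Tensor
from .swin import TokenGrid, Triple, _triple


@dataclass
class PatchEmbedConfig:
    patch_size: int = 4
    in_channels: int = 4
    embed_dim: int = 96

    def __post_init__(self):
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")


def tokens_to_volume(x: TokenGrid) -> Tensor:
    """(B, d*h*w, C) tokens -> (B, C, d, h, w) dense volume."""
    d, h, w = x.grid_dims
    B, _, C = x.values.shape
    return x.values.reshape(B, d, h, w, C).transpose(0, 4, 1, 2, 3)


def volume_to_tokens(v: Tensor) -> TokenGrid:
    """(B, C, d, h, w) dense volume -> row-major (d, h, w) tokens."""
    B, C, d, h, w = v.shape
    return TokenGrid(v.transpose(0, 2, 3, 4, 1).reshape(B, d * h * w, C), (d, h, w))


class PatchEmbed(Module):
    """Strided P^3 projection of a volume into a token grid.

    Equivalent to a conv with kernel P, stride P and C output channels;
    implemented as a linear map over flattened patches.  Trailing voxels that
    do not fill a whole patch are dropped (floor semantics).
    """

    def __init__(self, cfg: PatchEmbedConfig, rng: np.random.Generator,
                 bias: bool = True):
        self.cfg = cfg
        P, K, C = cfg.patch_size, cfg.in_channels, cfg.embed_dim
        self.proj = Linear(K * P ** 3, C, rng, bias=bias)

    def forward(self, volume: Tensor) -> TokenGrid:
        P, K = self.cfg.patch_size, self.cfg.in_channels
        if volume.ndim == 4:
            volume = volume.reshape(1, *volume.shape)
        B, Kv, D, H, W = volume.shape
        if Kv != K:
            raise ValueError(f"expected {K} channels, got {Kv}")
        if min(D, H, W) < P:
            raise ValueError(f"volume dims {(D, H, W)} smaller than patch {P}")
        d, h, w = D // P, H // P, W // P
        v = volume[:, :, :d * P, :h * P, :w * P]
        v = v.reshape(B, K, d, P, h, P, w, P)
        v = v.transpose(0, 2, 4, 6, 1, 3, 5, 7).reshape(B, d * h * w, K * P ** 3)
        return TokenGrid(self.proj(v), (d, h, w))


def patch_embed(volume: Tensor, embed: PatchEmbed) -> TokenGrid:
    """Functional alias for :meth:`PatchEmbed.forward`."""
    return embed(volume)


class PatchMerging(Module):
    """Downsample by 2 per axis: concat 2x2x2 tokens -> LN -> linear 8C->2C."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.dim = dim
        self.norm = LayerNorm(8 * dim)
        self.reduction = Linear(8 * dim, 2 * dim, rng, bias=False)

    def forward(self, x: TokenGrid) -> TokenGrid:
        d, h, w = x.grid_dims
        B, _, C = x.values.shape
        if C != self.dim:
            raise ValueError(f"expected width {self.dim}, got {C}")
        v = x.values.reshape(B, d, h, w, C)
        pads = (d % 2, h % 2, w % 2)
        if any(pads):
            v = v.pad(((0, 0), (0, pads[0]), (0, pads[1]), (0, pads[2]), (0, 0)))
            d, h, w = d + pads[0], h + pads[1], w + pads[2]
        v = v.reshape(B, d // 2, 2, h // 2, 2, w // 2, 2, C)
        v = v.transpose(0, 1, 3, 5, 2, 4, 6, 7)
        v = v.reshape(B, (d // 2) * (h // 2) * (w // 2), 8 * C)
        return TokenGrid(self.reduction(self.norm(v)), (d // 2, h // 2, w // 2))


class PatchExpanding(Module):
    """Upsample by 2 per axis: linear C->2C, scatter into 2x2x2 sub-tokens of
    width C/4, then LN."""

    def __init__(self, dim: int, rng: np.random.Generator,
                 out_dim: int | None = None):
        if out_dim is None:
            if dim % 4:
                raise ValueError(
                    f"patch expanding needs width divisible by 4, got {dim}")
            out_dim = dim // 4
        self.dim = dim
        self.out_dim = out_dim
        self.expand = Linear(dim, 8 * out_dim, rng, bias=False)
        self.norm = LayerNorm(out_dim)

    def forward(self, x: TokenGrid) -> TokenGrid:
        d, h, w = x.grid_dims
        B, _, C = x.values.shape
        if C != self.dim:
            raise ValueError(f"expected width {self.dim}, got {C}")
        co = self.out_dim
        v = self.expand(x.values).reshape(B, d, h, w, 2, 2, 2, co)
        v = v.transpose(0, 1, 4, 2, 5, 3, 6, 7)
        v = v.reshape(B, 8 * d * h * w, co)
        return TokenGrid(self.norm(v), (2 * d, 2 * h, 2 * w))


class PatchExpand(Module):
    """Factor-2 or factor-4 expansion; factor 4 cascades two factor-2 stages
    (C -> C/4 -> C/16)."""

    def __init__(self, dim: int, factor: int, rng: np.random.Generator):
        if factor not in (2, 4):
            raise ValueError(f"expansion factor must be 2 or 4, got {factor}")
        self.factor = factor
        stages = [PatchExpanding(dim, rng)]
        if factor == 4:
            stages.append(PatchExpanding(dim // 4, rng))
        self.stages = stages

    @property
    def out_dim(self) -> int:
        return self.stages[-1].dim // 4

    def forward(self, x: TokenGrid) -> TokenGrid:
        for s in self.stages:
            x = s(x)
        return x


def patch_merge(x: TokenGrid, merge: PatchMerging) -> TokenGrid:
    return merge(x)


def patch_expand(x: TokenGrid, expand: PatchExpand) -> TokenGrid:
    return expand(x)
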
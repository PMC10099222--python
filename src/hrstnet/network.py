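"""HRSTNet: an HRNet-style multi-resolution 3D shifted-window transformer.

The network keeps a high-resolution token grid alive through the whole
forward pass instead of encode-then-decode.  Stage ``n`` runs ``n`` parallel
shifted-window transformer blocks on grids at strides 4, 8, ... (each block
followed by a patch-merging downsample); after every stage except the first,
a multi-resolution feature-fusion (MRFF) block resamples every branch to
every other branch's resolution, concatenates per resolution and refines
with a residual conv block.  The deepest merged map opens the next stage's
new branch.  The head upsamples the last MRFF's outputs to the finest grid,
fuses them, expands back to voxel resolution and classifies.

Variants HRSTNet-2/-3/-4 truncate the trunk after stage 2/3/4.  The fusion
blocks' hidden widths are the architecture's free parameter; the defaults
below are calibrated so that the three variants' trainable-parameter counts
and analytic GFLOPs reproduce the published complexity figures
(7.19/50.07/266.33 M parameters; 107.47/318.43 GFLOPs at a 4x128^3 input).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from ._tensor import (
    Conv3d, InstanceNorm3d, Module, ModuleList, Tensor, concat, count_macs,
    leaky_relu, no_grad,
)
from .swin import SwinBlock, SwinBlockConfig, TokenGrid, _triple
from .resample import (
    PatchEmbed, PatchEmbedConfig, PatchExpanding, PatchMerging,
    tokens_to_volume, volume_to_tokens,
)

__all__ = [
    "NetworkConfig", "HRSTNet", "build_network", "build_variant", "VARIANTS",
    "count_parameters", "count_flops", "complexity_summary",
    "save_checkpoint", "load_checkpoint",
]

# fusion hidden widths per MRFF level, calibrated against the published
# parameter counts of the three variants (see docs/methods.md)
FUSION_WIDTHS = {2: (98, 200), 3: (335, 147, 743), 4: (201, 201, 402, 1506)}
HEAD_WIDTH = {2: 226, 3: 74, 4: 100}
DEFAULT_HEADS = (3, 6, 12, 24)


@dataclass
class NetworkConfig:
    """Configuration of an HRSTNet variant.

    ``num_stages`` selects HRSTNet-2/-3/-4.  ``head_levels`` lists the
    resolution levels (1 = stride 4 ... 4 = stride 32) fused by the
    segmentation head; default all available levels.
    """

    num_stages: int = 4
    in_channels: int = 4
    num_classes: int = 4
    embed_dim: int = 96
    patch_size: int = 4
    depth: int = 2
    num_heads: Sequence[int] = DEFAULT_HEADS
    window_size: Sequence[int] = (7, 7, 7)
    mlp_ratio: float = 4.0
    qkv_bias: bool = True
    fusion_widths: dict | None = None
    head_width: int | None = None
    head_levels: Sequence[int] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.num_stages not in (2, 3, 4):
            raise ValueError(f"num_stages must be 2, 3 or 4, got {self.num_stages}")
        self.num_heads = tuple(self.num_heads)
        self.window_size = _triple(self.window_size)
        if len(self.num_heads) < self.num_stages:
            raise ValueError("need one head count per resolution level")
        for j in range(self.num_stages):
            if self.width(j + 1) % self.num_heads[j]:
                raise ValueError(
                    f"width {self.width(j + 1)} at level {j + 1} not divisible "
                    f"by {self.num_heads[j]} heads")
        if self.fusion_widths is None:
            if self.embed_dim == 96:
                self.fusion_widths = {k: FUSION_WIDTHS[k]
                                      for k in range(2, self.num_stages + 1)}
            else:
                self.fusion_widths = {
                    k: tuple(self.width(j) for j in range(1, k + 1))
                    for k in range(2, self.num_stages + 1)}
        else:
            self.fusion_widths = {int(k): tuple(v)
                                  for k, v in self.fusion_widths.items()}
        if self.head_width is None:
            self.head_width = (HEAD_WIDTH[self.num_stages]
                               if self.embed_dim == 96 else self.embed_dim)
        if self.head_levels is None:
            self.head_levels = tuple(range(1, self.num_stages + 1))
        else:
            self.head_levels = tuple(sorted(set(int(v) for v in self.head_levels)))
            if not self.head_levels:
                raise ValueError("head_levels must not be empty")
            if any(not 1 <= v <= self.num_stages for v in self.head_levels):
                raise ValueError(f"head_levels {self.head_levels} outside "
                                 f"1..{self.num_stages}")

    def width(self, level: int) -> int:
        """Channel width at resolution level (1-based)."""
        return self.embed_dim * 2 ** (level - 1)

    def stride(self, level: int) -> int:
        return self.patch_size * 2 ** (level - 1)

    def block_config(self, level: int) -> SwinBlockConfig:
        return SwinBlockConfig(depth=self.depth,
                               num_heads=self.num_heads[level - 1],
                               window_size=self.window_size,
                               mlp_ratio=self.mlp_ratio,
                               qkv_bias=self.qkv_bias)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fusion_widths"] = {str(k): list(v) for k, v in self.fusion_widths.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if d.get("fusion_widths"):
            d["fusion_widths"] = {int(k): tuple(v)
                                  for k, v in d["fusion_widths"].items()}
        return cls(**d)


class ResidualBlock(Module):
    """conv3-IN-LReLU-conv3-IN with a projected identity, as used in
    medical-image segmentation decoders."""

    def __init__(self, in_ch: int, out_ch: int, hidden: int,
                 rng: np.random.Generator):
        self.conv1 = Conv3d(in_ch, hidden, 3, rng, bias=False)
        self.norm1 = InstanceNorm3d(hidden)
        self.conv2 = Conv3d(hidden, out_ch, 3, rng, bias=False)
        self.norm2 = InstanceNorm3d(out_ch)
        if in_ch != out_ch:
            self.skip = Conv3d(in_ch, out_ch, 1, rng, bias=False)
            self.skip_norm = InstanceNorm3d(out_ch)
        else:
            self.skip = None

    def forward(self, v: Tensor) -> Tensor:
        y = leaky_relu(self.norm1(self.conv1(v)), 0.01)
        y = self.norm2(self.conv2(y))
        s = self.skip_norm(self.skip(v)) if self.skip is not None else v
        return leaky_relu(y + s, 0.01)


def _up_width(width: int, steps: int) -> int:
    """Channel width after ``steps`` patch expands (each quarters the width,
    floored at 1)."""
    for _ in range(steps):
        width = max(width // 4, 1)
    return width


class Stage(Module):
    """Stage ``index``: one transformer block per live branch, each followed
    by a patch merge.  The last stage omits the deepest merge (its output
    would have no consumer)."""

    def __init__(self, index: int, cfg: NetworkConfig, is_last: bool,
                 rng: np.random.Generator):
        self.index = index
        self.is_last = is_last
        self.blocks = ModuleList([
            SwinBlock(cfg.width(j), cfg.block_config(j), rng)
            for j in range(1, index + 1)])
        n_merge = index - 1 if is_last else index
        self.merges = ModuleList([
            PatchMerging(cfg.width(j), rng) for j in range(1, n_merge + 1)])

    def forward(self, features: list[TokenGrid]) -> tuple[list[TokenGrid],
                                                          list[TokenGrid]]:
        if len(features) != self.index:
            raise ValueError(f"stage {self.index} expects {self.index} feature "
                             f"maps, got {len(features)}")
        outs = [blk(f) for blk, f in zip(self.blocks, features)]
        merged = [mrg(o) for mrg, o in zip(self.merges, outs)]
        return outs, merged


class MRFF(Module):
    """Multi-resolution feature fusion over ``k`` branches.

    Every branch is resampled to every other branch's resolution: coarser
    targets by chained patch merges (the first step of each chain is the
    producing stage's own merge, passed in as a seed), finer targets by
    chained patch expands (each expand quarters the width).  Maps of equal
    resolution are concatenated and refined by a residual block back to the
    branch width.
    """

    def __init__(self, k: int, cfg: NetworkConfig, rng: np.random.Generator):
        self.k = k
        widths = cfg.fusion_widths[k]
        if len(widths) != k:
            raise ValueError(f"fusion_widths[{k}] must list {k} widths")
        self.down = ModuleList()   # per source i: merges for levels i+2..k
        self.up = ModuleList()     # per source i: expands for levels i-1..1
        for i in range(1, k + 1):
            self.down.append(ModuleList(
                [PatchMerging(cfg.width(j - 1), rng) for j in range(i + 2, k + 1)]))
            ups, wdt = [], cfg.width(i)
            for _ in range(i - 1):
                out = max(wdt // 4, 1)
                ups.append(PatchExpanding(wdt, rng, out_dim=out))
                wdt = out
            self.up.append(ModuleList(ups))
        self.fuse = ModuleList()
        for j in range(1, k + 1):
            w_in = j * cfg.width(j) + sum(_up_width(cfg.width(i), i - j)
                                          for i in range(j + 1, k + 1))
            self.fuse.append(ResidualBlock(w_in, cfg.width(j), widths[j - 1], rng))

    def forward(self, block_outs: list[TokenGrid],
                seeds: list[TokenGrid]) -> list[TokenGrid]:
        k = self.k
        if len(block_outs) != k or len(seeds) != k - 1:
            raise ValueError(f"MRFF-{k} expects {k} branch maps and {k - 1} "
                             f"merged seeds")
        maps = [dict() for _ in range(k)]   # maps[i-1][j] = source i at level j
        for i in range(1, k + 1):
            maps[i - 1][i] = block_outs[i - 1]
            if i < k:
                maps[i - 1][i + 1] = seeds[i - 1]
            cur = seeds[i - 1] if i < k else None
            for step, mrg in enumerate(self.down[i - 1]):
                cur = mrg(cur)
                maps[i - 1][i + 2 + step] = cur
            cur = block_outs[i - 1]
            for step, exp in enumerate(self.up[i - 1]):
                cur = exp(cur)
                maps[i - 1][i - 1 - step] = cur
        fused = []
        for j in range(1, k + 1):
            vols = [tokens_to_volume(maps[i - 1][j]) for i in range(1, k + 1)]
            out = self.fuse[j - 1](concat(vols, axis=1))
            fused.append(volume_to_tokens(out))
        return fused


class Head(Module):
    """Segmentation head: upsample the selected fusion outputs to the finest
    grid, concatenate, refine with a residual block, expand back to voxel
    resolution (two 2x stages) and classify with a 1^3 conv."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.levels = cfg.head_levels
        self.chains = ModuleList()
        w_in = 0
        for j in self.levels:
            ups, wdt = [], cfg.width(j)
            for _ in range(j - 1):
                out = max(wdt // 4, 1)
                ups.append(PatchExpanding(wdt, rng, out_dim=out))
                wdt = out
            self.chains.append(ModuleList(ups))
            w_in += wdt
        C1 = cfg.embed_dim
        self.fuse = ResidualBlock(w_in, C1, cfg.head_width, rng)
        c2 = max(C1 // 4, 4)
        self.up1 = PatchExpanding(C1, rng, out_dim=c2)
        c3 = max(c2 // 4, 4)
        self.up2 = PatchExpanding(c2, rng, out_dim=c3)
        self.classifier = Conv3d(c3, cfg.num_classes, 1, rng, bias=True)

    def forward(self, fused: list[TokenGrid]) -> Tensor:
        gathered = []
        for chain, j in zip(self.chains, self.levels):
            cur = fused[j - 1]
            for exp in chain:
                cur = exp(cur)
            gathered.append(tokens_to_volume(cur))
        x = volume_to_tokens(self.fuse(concat(gathered, axis=1)))
        x = self.up2(self.up1(x))
        return self.classifier(tokens_to_volume(x))


class HRSTNet(Module):
    """End-to-end network; ``forward`` maps (B, K, D, H, W) volumes to
    (B, num_classes, D, H, W) class scores."""

    def __init__(self, cfg: NetworkConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        n = cfg.num_stages
        self.patch_embed = PatchEmbed(
            PatchEmbedConfig(cfg.patch_size, cfg.in_channels, cfg.embed_dim), rng)
        self.stages = ModuleList([
            Stage(k, cfg, is_last=(k == n), rng=rng) for k in range(1, n + 1)])
        self.mrffs = ModuleList([MRFF(k, cfg, rng) for k in range(2, n + 1)])
        self.head = Head(cfg, rng)

    def forward(self, volume: Tensor) -> Tensor:
        if not isinstance(volume, Tensor):
            volume = Tensor(volume)
        squeeze = volume.ndim == 4
        if squeeze:
            volume = volume.reshape(1, *volume.shape)
        n = self.cfg.num_stages
        feats = [self.patch_embed(volume)]
        fused = None
        for k in range(1, n + 1):
            outs, merged = self.stages[k - 1](feats)
            if k == 1:
                feats = [outs[0], merged[0]]
            elif k < n:
                fused = self.mrffs[k - 2](outs, merged[:-1])
                feats = fused + [merged[-1]]
            else:
                fused = self.mrffs[k - 2](outs, merged)
        scores = self.head(fused)
        if squeeze:
            scores = scores.reshape(*scores.shape[1:])
        return scores


VARIANTS = {"hrstnet2": 2, "hrstnet3": 3, "hrstnet4": 4}


def build_network(cfg: NetworkConfig) -> HRSTNet:
    return HRSTNet(cfg)


def build_variant(name: str, **overrides) -> HRSTNet:
    """Build a preset variant (``hrstnet2`` / ``hrstnet3`` / ``hrstnet4``)."""
    key = name.lower().replace("-", "")
    if key not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")
    return HRSTNet(NetworkConfig(num_stages=VARIANTS[key], **overrides))


def count_parameters(model: Module) -> int:
    """Exact count of trainable scalars."""
    return model.num_parameters()


def params_millions(model: Module) -> float:
    return round(count_parameters(model) / 1e6, 2)


def count_flops(model: HRSTNet, input_shape: Sequence[int]) -> int:
    """Analytic MAC count of one forward pass at ``input_shape`` (K, D, H, W).

    Counts projection layers only (dense and convolutional), mirroring
    hook-based model-complexity counters; attention score products,
    normalisations and activations are excluded.
    """
    K, D, H, W = input_shape
    with no_grad(), count_macs() as c:
        model(Tensor(np.zeros((1, K, D, H, W), dtype=np.float32)))
    return c.total


def gflops(model: HRSTNet, input_shape: Sequence[int]) -> float:
    return round(count_flops(model, input_shape) / 1e9, 2)


def complexity_summary(model: HRSTNet,
                       input_shape: Sequence[int] | None = None) -> dict:
    out = {"parameters": count_parameters(model),
           "params_millions": params_millions(model)}
    if input_shape is not None:
        out["macs"] = count_flops(model, input_shape)
        out["gflops"] = round(out["macs"] / 1e9, 2)
    return out


def save_checkpoint(model: HRSTNet, path: str, extra: dict | None = None) -> None:
    state = model.state_dict()
    meta = {"config": model.cfg.to_dict(), "extra": extra or {}}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str) -> tuple[HRSTNet, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = HRSTNet(NetworkConfig.from_dict(meta["config"]))
    model.load_state_dict(state)
    return model, meta["extra"]
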
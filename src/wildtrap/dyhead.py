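"""Dynamic detection head: scale-, spatial- and task-aware attention.

The three pyramid levels are projected to a common channel width and
bilinearly resized to the middle (stride-16) level, forming a unified
level x space x channel tensor.  Each DyHead block then applies in sequence

* scale-aware attention  (pi_L): one scalar gate per level,
  ``hard_sigmoid(linear(mean(F)))`` with ``hard_sigmoid(x) = clamp((x+1)/2, 0, 1)``;
* spatial-aware attention (pi_S): a 3 x 3 modulated deformable aggregation
  (K = 9 sampling points, learned offsets, sigmoid-bounded modulation masks)
  with the offset/mask branch computed from the middle level and the
  aggregation weights shared across levels;
* task-aware attention   (pi_C): per channel,
  ``max(alpha1 * F_c + beta1, alpha2 * F_c + beta2)`` with the four
  coefficients produced from globally pooled features by two FC layers and
  a hard-tanh normalization to [-1, 1], initialized to the identity
  ``(alpha1, alpha2, beta1, beta2) = (1, 0, 0, 0)``.

Blocks are stackable; after the stack the levels are resized back to their
native spatial sizes and projected back to their native channel widths, so
the downstream decoupled head is unchanged.  The offset/mask branch is
zero-initialized so training starts from the plain-convolution degenerate
case of the deformable aggregation.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .model_core import ModelConfig, backbone_channels


def hard_sigmoid(x: nn.Tensor) -> nn.Tensor:
    return ((x + 1.0) * 0.5).clip(0.0, 1.0)


def default_unified_channels(width_multiple: float) -> int:
    return max(int(round(128 * width_multiple / 0.5)), 1)


class ScaleAttention(nn.Module):
    """Per-level scalar gate from the level's global mean statistic."""

    def __init__(self):
        super().__init__()
        self.fc = nn.Linear(1, 1)
        self.fc.weight.data[...] = 0.0          # zero init -> gate 0.5
        self.fc.bias.data[...] = 0.0

    def forward(self, levels: list[nn.Tensor]) -> list[nn.Tensor]:
        out = []
        for f in levels:
            stat = f.mean(axis=(1, 2, 3)).reshape(-1, 1)      # (N, 1)
            gate = hard_sigmoid(self.fc(stat)).reshape(-1, 1, 1, 1)
            out.append(f * gate)
        return out


class SpatialAttention(nn.Module):
    """Modulated 3x3 deformable aggregation, shared across levels.

    Offsets (2K) and modulation logits (K) come from a 3x3 conv branch on
    the middle level; modulation is sigmoid-bounded to [0, 1].
    """

    def __init__(self, channels: int):
        super().__init__()
        self.channels = channels
        self.offset_conv = nn.Conv2d(channels, 27, 3)
        self.offset_conv.weight.data[...] = 0.0
        self.offset_conv.bias.data[...] = 0.0
        self.weight = nn.Parameter(
            nn._INIT_RNG.normal(0.0, np.sqrt(2.0 / (9 * channels)), (channels, channels, 3, 3)))
        self.bias = nn.Parameter(np.zeros(channels))

    def _aggregate(self, f: nn.Tensor, offsets: nn.Tensor, mask: nn.Tensor) -> nn.Tensor:
        n, c, h, w = f.shape
        sampled = nn.deform_sample3x3(f, offsets)             # (N, C, 9, H, W)
        sampled = sampled * mask.reshape(n, 1, 9, h, w)
        sm = sampled.reshape(n, c * 9, h * w).transpose(1, 0, 2).reshape(c * 9, n * h * w)
        wm = self.weight.reshape(c, c * 9)
        out = (wm @ sm).reshape(c, n, h, w).transpose(1, 0, 2, 3)
        return out + self.bias.reshape(1, c, 1, 1)

    def forward(self, levels: list[nn.Tensor]) -> list[nn.Tensor]:
        mid = levels[len(levels) // 2]
        branch = self.offset_conv(mid)
        offsets = branch[:, :18]
        mask = branch[:, 18:].sigmoid()
        return [self._aggregate(f, offsets, mask) for f in levels]


class TaskAttention(nn.Module):
    """Channel-wise piecewise-linear gating (a learnable ReLU generalization)."""

    def __init__(self, channels: int, reduction: int = 4):
        super().__init__()
        self.channels = channels
        self.fc1 = nn.Linear(channels, max(channels // reduction, 4))
        self.fc2 = nn.Linear(max(channels // reduction, 4), 4 * channels)
        self.fc2.weight.data[...] = 0.0          # identity at initialization
        self.fc2.bias.data[...] = 0.0
        init = np.zeros((4, channels), dtype=np.float32)
        init[0] = 1.0                            # (alpha1, alpha2, beta1, beta2) = (1,0,0,0)
        self._coeff_init = init.reshape(-1)

    def coefficients(self, levels: list[nn.Tensor]) -> nn.Tensor:
        pooled = [f.mean(axis=(2, 3)) for f in levels]        # (N, C) each
        stat = pooled[0]
        for p in pooled[1:]:
            stat = stat + p
        stat = stat * (1.0 / len(pooled))
        raw = self.fc2(nn.maximum(self.fc1(stat), 0.0))
        # hard-tanh normalization to [-1, 1] around the identity initializer
        return (raw + self._coeff_init).clip(-1.0, 1.0)       # (N, 4C)

    def forward(self, levels: list[nn.Tensor]) -> list[nn.Tensor]:
        n = levels[0].shape[0]
        c = self.channels
        coef = self.coefficients(levels).reshape(n, 4, c)
        a1 = coef[:, 0].reshape(n, c, 1, 1)
        a2 = coef[:, 1].reshape(n, c, 1, 1)
        b1 = coef[:, 2].reshape(n, c, 1, 1)
        b2 = coef[:, 3].reshape(n, c, 1, 1)
        return [nn.maximum(f * a1 + b1, f * a2 + b2) for f in levels]


class DyHeadBlock(nn.Module):
    """One [scale -> spatial -> task] attention block on the unified tensor."""

    def __init__(self, channels: int, enable_scale=True, enable_spatial=True, enable_task=True):
        super().__init__()
        self.scale = ScaleAttention() if enable_scale else None
        self.spatial = SpatialAttention(channels) if enable_spatial else None
        self.task = TaskAttention(channels) if enable_task else None

    def forward(self, levels):
        if self.scale is not None:
            levels = self.scale(levels)
        if self.spatial is not None:
            levels = self.spatial(levels)
        if self.task is not None:
            levels = self.task(levels)
        return levels


class DyHead(nn.Module):
    """Unify pyramid -> N stacked attention blocks -> restore native shapes."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        from .model_core import BaseConv  # local import to avoid cycle at module load

        dc = config.dyhead
        u = dc.unified_channels or default_unified_channels(config.width_multiple)
        self.unified_channels = u
        in_ch = backbone_channels(config.width_multiple)
        self.in_proj = nn.ModuleList([BaseConv(c, u, 1, act=False) for c in in_ch])
        self.out_proj = nn.ModuleList([BaseConv(u, c, 1, act=False) for c in in_ch])
        self.blocks = nn.ModuleList([
            DyHeadBlock(u, dc.enable_scale, dc.enable_spatial, dc.enable_task)
            for _ in range(config.dyhead_stacks)
        ])

    def forward(self, feats: list[nn.Tensor]) -> list[nn.Tensor]:
        if not self.blocks:
            return feats
        native_hw = [f.shape[2:] for f in feats]
        mid_hw = native_hw[len(feats) // 2]
        levels = [nn.resize_bilinear(proj(f), mid_hw) for proj, f in zip(self.in_proj, feats)]
        for blk in self.blocks:
            levels = blk(levels)
        return [proj(nn.resize_bilinear(f, hw))
                for proj, f, hw in zip(self.out_proj, levels, native_hw)]


def dyhead_forward(feats: list[nn.Tensor], stacks: int,
                   config: ModelConfig | None = None, seed: int = 0) -> list[nn.Tensor]:
    """Apply a freshly built ``stacks``-deep dynamic head to a pyramid.

    ``stacks = 0`` is the identity (no modules are built at all).
    """
    if stacks < 0:
        raise ValueError("stacks must be >= 0")
    if stacks == 0:
        return feats
    cfg = config or ModelConfig()
    cfg = ModelConfig.from_dict({**cfg.to_dict(), "dyhead_stacks": stacks})
    with nn.init_rng(np.random.default_rng(seed)):
        head = DyHead(cfg)
    return head(feats)
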
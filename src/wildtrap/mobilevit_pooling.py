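"""MobileViT-style local-global refinement block with a pooling token mixer.

The block follows the MobileViT layout — local n x n convolution, 1 x 1
projection to a transformer width d, global modeling, projection back,
shortcut concatenation and fusion — but the transformer's multi-head
self-attention is replaced by a *parameter-free* spatial pooling operator
(the MetaFormer/PoolFormer token mixer):  ``mixer(x) = AvgPool(x) - x``.
A single such layer is used (depth 1).

Two placement modes exist for refining the three backbone feature levels:

* ``embedded``       — one block after each of the last three backbone
                       stages, inside the backbone (CNN and token-mixer
                       blocks alternate);
* ``after_backbone`` — one block per level between the backbone outputs
                       and the neck (global modeling strictly after the CNN).

Both modes use the same three blocks, so their parameter counts are equal.

The transformer width defaults to ``d = round(1.104 * c)`` per level,
calibrated once so the three blocks at width 0.50 add ~13.4 M parameters,
the published budget of this refinement stage; ``d`` and the other knobs
are exposed in the ``refine:`` config section.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .model_core import BaseConv, CSPDarknet, ConfigError, ModelConfig, backbone_channels


def default_mixer_dim(in_channels: int) -> int:
    """Default transformer width per level (see module docstring)."""
    return int(round(1.104 * in_channels))


@dataclass
class MVPBlockConfig:
    """Configuration of one refinement block on a ``c``-channel level."""

    in_channels: int
    mixer_dim: int | None = None      # d; None -> default_mixer_dim(c)
    patch_size: int = 2
    local_kernel: int = 3
    pool_kernel: int = 3
    mlp_ratio: float = 4.0
    fusion_kernel: str = "nxn"        # "nxn" (standard) or "nx1" (as-printed variant)
    depth: int = 1                    # single transformer layer, fixed

    def __post_init__(self):
        if self.depth != 1:
            raise ConfigError("depth is fixed to 1 (single transformer layer)")
        if self.pool_kernel % 2 == 0:
            raise ConfigError("pool_kernel must be odd")
        if self.mixer_dim is None:
            self.mixer_dim = default_mixer_dim(self.in_channels)


def pooling_token_mixer(x: nn.Tensor, pool_kernel: int = 3) -> nn.Tensor:
    """Parameter-free token mixer: average pooling minus identity.

    Stride-1 'same' average pooling with border averages taken over the
    in-bounds window elements only; subtracting the input makes the operator
    zero-mean on locally constant signals, so a spatially constant map (and
    any map with ``pool_kernel=1``) is mixed to exactly zero.
    """
    if pool_kernel % 2 == 0:
        raise ConfigError("pool_kernel must be odd")
    if pool_kernel == 1:
        return x - x
    return nn.avgpool2d_same(x, pool_kernel) - x


class PoolingMixer(nn.Module):
    """Module wrapper of :func:`pooling_token_mixer` (zero parameters)."""

    def __init__(self, pool_kernel: int = 3):
        super().__init__()
        if pool_kernel % 2 == 0:
            raise ConfigError("pool_kernel must be odd")
        self.pool_kernel = pool_kernel

    def forward(self, x):
        return pooling_token_mixer(x, self.pool_kernel)


class IdentityMixer(nn.Module):
    """Degenerate mixer used in ablations; same (zero) parameter count."""

    def forward(self, x):
        return x


def unfold_patches(x: nn.Tensor, patch: int) -> nn.Tensor:
    """(N, C, H, W) -> patch tokens (N, C, patch*patch, H/patch * W/patch)."""
    n, c, h, w = x.shape
    if h % patch or w % patch:
        raise ValueError(
            f"spatial dims {(h, w)} not divisible by patch size {patch}; pad the input first")
    hp, wp = h // patch, w // patch
    t = x.reshape(n, c, hp, patch, wp, patch)
    t = t.transpose(0, 1, 3, 5, 2, 4)  # N, C, p, p, Hp, Wp
    return t.reshape(n, c, patch * patch, hp * wp)


def fold_patches(tokens: nn.Tensor, patch: int, hw: tuple[int, int]) -> nn.Tensor:
    """Inverse of :func:`unfold_patches`."""
    n, c, pp, L = tokens.shape
    h, w = hw
    hp, wp = h // patch, w // patch
    t = tokens.reshape(n, c, patch, patch, hp, wp)
    t = t.transpose(0, 1, 4, 2, 5, 3)  # N, C, Hp, p, Wp, p
    return t.reshape(n, c, h, w)


class MVPBlock(nn.Module):
    """One local-global refinement block (shape preserving, c -> c channels).

    Pipeline: n x n local conv -> 1 x 1 proj (c -> d) -> unfold to patch
    tokens -> one MetaFormer layer (token-norm + pooling mixer, residual;
    token-norm + 2-layer MLP d -> r*d -> d, residual) -> fold -> 1 x 1 proj
    (d -> c) -> concat with the block input -> n x n fusion conv (2c -> c).
    The mixer's neighborhood is spatial, i.e. it acts on the folded 2-D map.
    """

    def __init__(self, cfg: MVPBlockConfig, mixer: nn.Module | None = None):
        super().__init__()
        c, d, nk = cfg.in_channels, cfg.mixer_dim, cfg.local_kernel
        hidden = int(round(cfg.mlp_ratio * d))
        self.cfg = cfg
        self.local = BaseConv(c, c, nk)
        self.proj_in = BaseConv(c, d, 1)
        self.norm1 = nn.LayerNormChannel(d)
        self.mixer = mixer if mixer is not None else PoolingMixer(cfg.pool_kernel)
        self.norm2 = nn.LayerNormChannel(d)
        self.mlp1 = nn.Conv2d(d, hidden, 1)
        self.mlp2 = nn.Conv2d(hidden, d, 1)
        self.proj_out = BaseConv(d, c, 1)
        fk = nk if cfg.fusion_kernel == "nxn" else (nk, 1)
        self.fusion = BaseConv(2 * c, c, fk)

    def forward(self, x):
        n, c, h, w = x.shape
        p = self.cfg.patch_size
        y = self.proj_in(self.local(x))
        # global modeling: unfold -> metaformer layer -> fold
        tokens = unfold_patches(y, p)
        y = fold_patches(tokens, p, (h, w))
        y = y + self.mixer(self.norm1(y))
        y = y + self.mlp2(self.mlp1(self.norm2(y)).silu())
        y = self.proj_out(y)
        return self.fusion(nn.concat([x, y], axis=1))


def mvp_block_forward(x: nn.Tensor, cfg: MVPBlockConfig, seed: int = 0) -> nn.Tensor:
    """Build a block from ``cfg`` (deterministic per seed) and run it on ``x``."""
    with nn.init_rng(np.random.default_rng(seed)):
        block = MVPBlock(cfg)
    return block(x)


def _blocks_for(config: ModelConfig) -> nn.ModuleList:
    rc = config.refine
    chans = backbone_channels(config.width_multiple)
    dims = rc.mixer_dims if rc.mixer_dims is not None else [None] * 3
    blocks = nn.ModuleList()
    for c, d in zip(chans, dims):
        blocks.append(MVPBlock(MVPBlockConfig(
            in_channels=c, mixer_dim=d, patch_size=rc.patch_size,
            local_kernel=rc.local_kernel, pool_kernel=rc.pool_kernel,
            mlp_ratio=rc.mlp_ratio, fusion_kernel=rc.fusion_kernel)))
    return blocks


class FeatureExtractor(nn.Module):
    """Backbone plus (optionally) refinement, producing the 3-level pyramid."""

    def __init__(self, backbone: CSPDarknet, mode: str, blocks: nn.ModuleList | None):
        super().__init__()
        self.backbone = backbone
        self.mode = mode
        if mode == "embedded":
            backbone.refine_blocks = blocks      # applied inside the backbone
            self.blocks = None
        else:
            self.blocks = blocks

    def forward(self, x):
        feats = self.backbone(x)
        if self.blocks is not None:
            feats = [blk(f) for blk, f in zip(self.blocks, feats)]
        return feats


def attach_refinement(backbone: CSPDarknet, mode: str,
                      config: ModelConfig | None = None) -> FeatureExtractor:
    """Wire refinement blocks around ``backbone`` according to ``mode``.

    ``none`` is the identity attachment; ``embedded`` interleaves one block
    after each of the last three backbone stages; ``after_backbone`` applies
    one block per pyramid level after the backbone.  The same three blocks
    are used either way, so total parameter counts are mode-independent.
    """
    if mode not in ("none", "embedded", "after_backbone"):
        raise ConfigError(f"unknown refine mode: {mode!r}")
    if mode == "none":
        return FeatureExtractor(backbone, mode, None)
    if config is None:
        config = ModelConfig()
    return FeatureExtractor(backbone, mode, _blocks_for(config))
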
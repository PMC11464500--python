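"""Anchor-free one-stage detector core: backbone, neck, decoupled head.

Assembles the small (depth 0.33 / width 0.50) variant of the YOLOX family:
a CSPDarknet backbone with a Focus stem and SPP bottleneck, a PAFPN neck,
and a decoupled classification/regression head predicting, per feature-map
location, 4 box-regression values, an objectness logit and per-class logits.
Optional feature-refinement blocks (:mod:`wildtrap.mobilevit_pooling`) and a
stackable dynamic head (:mod:`wildtrap.dyhead`) are inserted according to
the :class:`ModelConfig`.

Architecture accounting (trainable parameters, forward FLOPs) is exposed so
built networks can be compared against published model tables.  FLOPs count
each fused multiply-accumulate of a convolution / linear layer as 2 FLOPs
(one multiply plus one add); parameter-free operations are free.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import nn

STRIDES = (8, 16, 32)


class ConfigError(ValueError):
    """Invalid model configuration; the message names the offending field."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RefineConfig:
    """Hyperparameters of the pooling-token-mixer refinement blocks."""

    patch_size: int = 2
    local_kernel: int = 3
    pool_kernel: int = 3
    mlp_ratio: float = 4.0
    #: transformer (mixer) width per pyramid level; None selects the default
    #: d = round(1.104 * c), calibrated to the published parameter budget.
    mixer_dims: tuple | None = None
    #: final fusion kernel: "nxn" (standard MobileViT) or "nx1"
    fusion_kernel: str = "nxn"


@dataclass
class DyHeadAttnConfig:
    unified_channels: int | None = None  # default 128 * (width / 0.5)
    enable_scale: bool = True
    enable_spatial: bool = True
    enable_task: bool = True


@dataclass
class LossConfig:
    box_weight: float = 5.0
    cls_weight: float = 1.0
    obj_weight: float = 1.0


BOX_LOSS_VARIANTS = ("iou", "focal_iou", "giou", "diou", "ciou")
REFINE_MODES = ("none", "embedded", "after_backbone")


@dataclass
class ModelConfig:
    """Full architectural description; two equal configs build identical nets."""

    depth_multiple: float = 0.33
    width_multiple: float = 0.50
    num_classes: int = 9
    input_size: int = 640
    refine_mode: str = "after_backbone"
    dyhead_stacks: int = 2
    box_loss: str = "focal_iou"
    focal_gamma: float = 0.5
    refine: RefineConfig = field(default_factory=RefineConfig)
    dyhead: DyHeadAttnConfig = field(default_factory=DyHeadAttnConfig)
    loss: LossConfig = field(default_factory=LossConfig)

    def validate(self) -> "ModelConfig":
        if self.depth_multiple <= 0:
            raise ConfigError("depth_multiple must be > 0")
        if self.width_multiple <= 0:
            raise ConfigError("width_multiple must be > 0")
        if self.num_classes < 1:
            raise ConfigError("num_classes must be >= 1")
        if self.input_size % 32 != 0:
            raise ConfigError("input_size must be divisible by 32")
        if self.refine_mode not in REFINE_MODES:
            raise ConfigError(f"refine_mode must be one of {REFINE_MODES}")
        if self.dyhead_stacks < 0:
            raise ConfigError("dyhead_stacks must be >= 0")
        if self.box_loss not in BOX_LOSS_VARIANTS:
            raise ConfigError(f"box_loss must be one of {BOX_LOSS_VARIANTS}")
        if self.focal_gamma < 0:
            raise ConfigError("focal_gamma must be >= 0")
        if self.refine.pool_kernel % 2 == 0:
            raise ConfigError("refine.pool_kernel must be odd")
        if self.refine.fusion_kernel not in ("nxn", "nx1"):
            raise ConfigError("refine.fusion_kernel must be 'nxn' or 'nx1'")
        return self

    # -- presets -----------------------------------------------------------
    @classmethod
    def baseline(cls, **kw) -> "ModelConfig":
        """Plain small-variant baseline: no refinement, no dynamic head."""
        kw.setdefault("refine_mode", "none")
        kw.setdefault("dyhead_stacks", 0)
        kw.setdefault("box_loss", "iou")
        return cls(**kw).validate()

    @classmethod
    def improved(cls, **kw) -> "ModelConfig":
        """Refined + dynamic-head + Focal-IoU model (the package default)."""
        return cls(**kw).validate()

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key, sub in (("refine", RefineConfig), ("dyhead", DyHeadAttnConfig), ("loss", LossConfig)):
            if key in d and isinstance(d[key], dict):
                dd = dict(d[key])
                if key == "refine" and dd.get("mixer_dims") is not None:
                    dd["mixer_dims"] = tuple(dd["mixer_dims"])
                d[key] = sub(**dd)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d).validate()

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _scale_width(ch: int, width: float) -> int:
    return max(int(round(ch * width)), 1)


def backbone_channels(width: float) -> tuple[int, int, int]:
    """Channels of the three backbone output levels (strides 8, 16, 32)."""
    return tuple(_scale_width(c, width) for c in (256, 512, 1024))


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class FeaturePyramid:
    """Ordered multi-scale feature maps at strides 8, 16, 32."""

    levels: list
    strides: tuple = STRIDES

    def __post_init__(self):
        if len(self.levels) != 3:
            raise ValueError(f"FeaturePyramid needs exactly 3 levels, got {len(self.levels)}")

    def validate(self, input_size: int | None = None) -> "FeaturePyramid":
        for lvl, s in zip(self.levels, self.strides):
            n, c, h, w = lvl.shape
            if input_size is not None and (h != input_size // s or w != input_size // s):
                raise ValueError(f"level at stride {s} has spatial dims {(h, w)}, "
                                 f"expected {input_size // s}")
        return self


@dataclass
class BoxSet:
    """Axis-aligned boxes: (x_min, y_min, x_max, y_max), 0-based continuous
    pixel coordinates, origin top-left.  ``scores`` is None for ground truth."""

    boxes: np.ndarray          # (M, 4) float32
    labels: np.ndarray         # (M,)  int64
    scores: np.ndarray | None = None

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=np.float32).reshape(-1, 4)
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=np.float32).reshape(-1)

    def __len__(self):
        return len(self.boxes)

    def validate(self) -> "BoxSet":
        if len(self.boxes) != len(self.labels):
            raise ValueError("boxes and labels length mismatch")
        if len(self.boxes):
            if not (self.boxes[:, 2] > self.boxes[:, 0]).all() or not (self.boxes[:, 3] > self.boxes[:, 1]).all():
                raise ValueError("every box must satisfy x_max > x_min and y_max > y_min")
        if self.scores is not None:
            if len(self.scores) != len(self.boxes):
                raise ValueError("scores length mismatch")
            if len(self.scores) and (self.scores.min() < 0 or self.scores.max() > 1):
                raise ValueError("scores must lie in [0, 1]")
        return self

    @classmethod
    def empty(cls) -> "BoxSet":
        return cls(np.zeros((0, 4)), np.zeros(0), np.zeros(0))


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


class BaseConv(nn.Module):
    """Conv -> BN -> SiLU (bias-free convolution)."""

    def __init__(self, c1, c2, k, s=1, act=True):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, stride=s, bias=False)  # 'same' padding
        self.bn = nn.BatchNorm2d(c2)
        self.act = act

    def forward(self, x):
        x = self.bn(self.conv(x))
        return x.silu() if self.act else x


class Focus(nn.Module):
    """Space-to-depth stem: 2x2 pixel de-interleave (3 -> 12 ch), then conv."""

    def __init__(self, c1, c2, k=3):
        super().__init__()
        self.conv = BaseConv(c1 * 4, c2, k, 1)

    def forward(self, x):
        tl = x[..., ::2, ::2]
        bl = x[..., 1::2, ::2]
        tr = x[..., ::2, 1::2]
        br = x[..., 1::2, 1::2]
        return self.conv(nn.concat([tl, bl, tr, br], axis=1))


class Bottleneck(nn.Module):
    def __init__(self, c1, c2, shortcut=True):
        super().__init__()
        self.conv1 = BaseConv(c1, c2, 1)
        self.conv2 = BaseConv(c2, c2, 3)
        self.use_add = shortcut and c1 == c2

    def forward(self, x):
        y = self.conv2(self.conv1(x))
        return y + x if self.use_add else y


class CSPLayer(nn.Module):
    """Cross-stage-partial layer with ``n`` bottlenecks on one branch."""

    def __init__(self, c1, c2, n=1, shortcut=True, expansion=0.5):
        super().__init__()
        ch = int(c2 * expansion)
        self.conv1 = BaseConv(c1, ch, 1)
        self.conv2 = BaseConv(c1, ch, 1)
        self.m = nn.Sequential(*[Bottleneck(ch, ch, shortcut) for _ in range(n)])
        self.conv3 = BaseConv(2 * ch, c2, 1)

    def forward(self, x):
        return self.conv3(nn.concat([self.m(self.conv1(x)), self.conv2(x)], axis=1))


class SPPBottleneck(nn.Module):
    """Spatial pyramid pooling with 5/9/13 stride-1 max pools."""

    def __init__(self, c1, c2, kernels=(5, 9, 13)):
        super().__init__()
        ch = c1 // 2
        self.conv1 = BaseConv(c1, ch, 1)
        self.kernels = kernels
        self.conv2 = BaseConv(ch * (len(kernels) + 1), c2, 1)

    def forward(self, x):
        x = self.conv1(x)
        pools = [x] + [nn.maxpool2d_same(x, k) for k in self.kernels]
        return self.conv2(nn.concat(pools, axis=1))


class CSPDarknet(nn.Module):
    """Backbone; returns features at strides 8, 16, 32.

    ``refine_blocks`` (set by ``attach_refinement`` in embedded mode) are
    applied after the last three stages, inside the backbone.
    """

    def __init__(self, depth: float, width: float):
        super().__init__()
        bc = _scale_width(64, width)
        bd = max(round(3 * depth), 1)
        self.stem = Focus(3, bc)
        self.dark2 = nn.Sequential(BaseConv(bc, bc * 2, 3, 2), CSPLayer(bc * 2, bc * 2, bd))
        self.dark3 = nn.Sequential(BaseConv(bc * 2, bc * 4, 3, 2), CSPLayer(bc * 4, bc * 4, bd * 3))
        self.dark4 = nn.Sequential(BaseConv(bc * 4, bc * 8, 3, 2), CSPLayer(bc * 8, bc * 8, bd * 3))
        self.dark5 = nn.Sequential(
            BaseConv(bc * 8, bc * 16, 3, 2),
            SPPBottleneck(bc * 16, bc * 16),
            CSPLayer(bc * 16, bc * 16, bd, shortcut=False),
        )
        self.refine_blocks: nn.ModuleList | None = None

    def forward(self, x):
        x = self.dark2(self.stem(x))
        c3 = self.dark3(x)
        c4 = self.dark4(c3)
        c5 = self.dark5(c4)
        if self.refine_blocks is not None:
            c3 = self.refine_blocks[0](c3)
            c4 = self.refine_blocks[1](c4)
            c5 = self.refine_blocks[2](c5)
        return [c3, c4, c5]


class PAFPN(nn.Module):
    """Path-aggregation FPN over the three backbone levels."""

    def __init__(self, depth: float, width: float):
        super().__init__()
        c3, c4, c5 = backbone_channels(width)
        bd = max(round(3 * depth), 1)
        self.lateral_conv0 = BaseConv(c5, c4, 1)
        self.C3_p4 = CSPLayer(2 * c4, c4, bd, shortcut=False)
        self.reduce_conv1 = BaseConv(c4, c3, 1)
        self.C3_p3 = CSPLayer(2 * c3, c3, bd, shortcut=False)
        self.bu_conv2 = BaseConv(c3, c3, 3, 2)
        self.C3_n3 = CSPLayer(2 * c3, c4, bd, shortcut=False)
        self.bu_conv1 = BaseConv(c4, c4, 3, 2)
        self.C3_n4 = CSPLayer(2 * c4, c5, bd, shortcut=False)

    def forward(self, feats):
        c3, c4, c5 = feats
        p5 = self.lateral_conv0(c5)
        p4 = self.C3_p4(nn.concat([nn.upsample_nearest2x(p5), c4], axis=1))
        p4r = self.reduce_conv1(p4)
        p3 = self.C3_p3(nn.concat([nn.upsample_nearest2x(p4r), c3], axis=1))
        n3 = self.C3_n3(nn.concat([self.bu_conv2(p3), p4r], axis=1))
        n4 = self.C3_n4(nn.concat([self.bu_conv1(n3), p5], axis=1))
        return [p3, n3, n4]


class DecoupledHead(nn.Module):
    """Per-level decoupled head: stem 1x1, two 3x3 conv towers, then 1x1
    predictors for class logits (nc), box regression (4) and objectness (1)."""

    def __init__(self, num_classes: int, width: float, in_channels):
        super().__init__()
        hid = _scale_width(256, width)
        self.num_classes = num_classes
        self.stems = nn.ModuleList()
        self.cls_convs = nn.ModuleList()
        self.reg_convs = nn.ModuleList()
        self.cls_preds = nn.ModuleList()
        self.reg_preds = nn.ModuleList()
        self.obj_preds = nn.ModuleList()
        prior = -math.log((1 - 0.01) / 0.01)  # rare-foreground prior for logits
        for c in in_channels:
            self.stems.append(BaseConv(c, hid, 1))
            self.cls_convs.append(nn.Sequential(BaseConv(hid, hid, 3), BaseConv(hid, hid, 3)))
            self.reg_convs.append(nn.Sequential(BaseConv(hid, hid, 3), BaseConv(hid, hid, 3)))
            cls_p = nn.Conv2d(hid, num_classes, 1)
            obj_p = nn.Conv2d(hid, 1, 1)
            cls_p.bias.data[...] = prior
            obj_p.bias.data[...] = prior
            self.cls_preds.append(cls_p)
            self.reg_preds.append(nn.Conv2d(hid, 4, 1))
            self.obj_preds.append(obj_p)

    def forward(self, feats):
        out = []
        for i, f in enumerate(feats):
            s = self.stems[i](f)
            cf = self.cls_convs[i](s)
            rf = self.reg_convs[i](s)
            out.append((self.reg_preds[i](rf), self.obj_preds[i](rf), self.cls_preds[i](cf)))
        return out


class DetectorModel(nn.Module):
    """Image batch -> per-level raw outputs (reg 4, obj 1, cls nc)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        from .dyhead import DyHead          # deferred: those modules import nn only
        from .mobilevit_pooling import attach_refinement

        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        with nn.init_rng(rng):
            backbone = CSPDarknet(config.depth_multiple, config.width_multiple)
            # the extractor owns the backbone (embedded blocks live inside it)
            self.extractor = attach_refinement(backbone, config.refine_mode, config)
            self.neck = PAFPN(config.depth_multiple, config.width_multiple)
            in_ch = backbone_channels(config.width_multiple)
            self.dyhead = DyHead(config) if config.dyhead_stacks > 0 else None
            self.head = DecoupledHead(config.num_classes, config.width_multiple, in_ch)

    @property
    def backbone(self) -> CSPDarknet:
        return self.extractor.backbone

    def extract_features(self, x) -> FeaturePyramid:
        """Backbone + refinement features (pre-neck), as a FeaturePyramid."""
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(x)
        return FeaturePyramid(self.extractor(x))

    def forward(self, x):
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(x)
        feats = self.extractor(x)
        feats = self.neck(feats)
        if self.dyhead is not None:
            feats = self.dyhead(feats)
        return self.head(feats)


def build_model(config: ModelConfig, seed: int = 0) -> DetectorModel:
    """Deterministically construct the detector described by ``config``."""
    return DetectorModel(config, seed=seed)


# ---------------------------------------------------------------------------
# accounting
# ---------------------------------------------------------------------------


def count_parameters(model: nn.Module) -> int:
    """Total trainable scalar parameter count."""
    return model.num_parameters()


def count_flops(model: DetectorModel, input_size: int | None = None) -> int:
    """Forward-pass FLOPs at ``input_size``.

    Convention (that of the profiling tools used for published YOLOX model
    tables): each convolution/linear multiply-accumulate counts 2 FLOPs and
    each normalization output element counts 4 (2 elementwise ops, doubled
    like the MACs); activations, pooling and resizing are free.
    """
    if input_size is None:
        input_size = model.config.input_size
    if input_size % 32 != 0:
        raise ConfigError("input_size must be divisible by 32")
    was_training = model.training
    model.eval()
    x = np.zeros((1, 3, input_size, input_size), dtype=np.float32)
    with nn.no_grad(), nn.count_macs() as ops:
        model(x)
    if was_training:
        model.train()
    return 2 * ops["macs"] + 4 * ops["norm"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    scale = 10 ** ndigits
    return math.floor(x * scale + 0.5) / scale


def params_millions(model: nn.Module) -> float:
    return round_half_up(count_parameters(model) / 1e6)


def flops_giga(model: DetectorModel, input_size: int | None = None) -> float:
    return round_half_up(count_flops(model, input_size) / 1e9)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def _level_grids(hsize: int, wsize: int, stride: int):
    ys, xs = np.meshgrid(np.arange(hsize), np.arange(wsize), indexing="ij")
    return xs.reshape(-1).astype(np.float32), ys.reshape(-1).astype(np.float32)


def flatten_raw_outputs(raw_outputs):
    """Flatten per-level raw maps into per-location arrays.

    Returns (reg (N,A,4), obj (N,A), cls (N,A,nc), centers (A,2), strides (A,)).
    """
    regs, objs, clss, cxs, cys, sts = [], [], [], [], [], []
    for (reg, obj, cls), stride in zip(raw_outputs, STRIDES):
        r = reg.data if isinstance(reg, nn.Tensor) else reg
        o = obj.data if isinstance(obj, nn.Tensor) else obj
        c = cls.data if isinstance(cls, nn.Tensor) else cls
        n, _, h, w = r.shape
        gx, gy = _level_grids(h, w, stride)
        regs.append(r.reshape(n, 4, -1).transpose(0, 2, 1))
        objs.append(o.reshape(n, -1))
        clss.append(c.reshape(n, c.shape[1], -1).transpose(0, 2, 1))
        cxs.append(gx)
        cys.append(gy)
        sts.append(np.full(h * w, stride, dtype=np.float32))
    reg = np.concatenate(regs, axis=1)
    obj = np.concatenate(objs, axis=1)
    cls = np.concatenate(clss, axis=1)
    grid = np.stack([np.concatenate(cxs), np.concatenate(cys)], axis=1)
    strides = np.concatenate(sts)
    return reg, obj, cls, grid, strides


def decode_boxes(reg: np.ndarray, grid: np.ndarray, strides: np.ndarray) -> np.ndarray:
    """Anchor-free decode: center = (grid + delta) * stride, size = exp(.) * stride."""
    cx = (grid[:, 0] + reg[..., 0]) * strides
    cy = (grid[:, 1] + reg[..., 1]) * strides
    w = np.exp(reg[..., 2]) * strides
    h = np.exp(reg[..., 3]) * strides
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=-1)


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of two (M,4)/(K,4) xyxy box arrays."""
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)), dtype=np.float32)
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(rb - lt, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0).astype(np.float32)


def nms_greedy(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Greedy NMS; returns kept indices sorted by descending score."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        ious = box_iou_matrix(boxes[i : i + 1], boxes[order[1:]])[0]
        order = order[1:][ious <= iou_threshold]
    return np.asarray(keep, dtype=np.int64)


def decode_predictions(raw_outputs, conf_threshold: float = 0.01,
                       nms_iou_threshold: float = 0.65,
                       input_size: int | None = None) -> list[BoxSet]:
    """Decode raw head outputs into one score-sorted BoxSet per batch image.

    Score = sigmoid(objectness) * sigmoid(class logit); detections below
    ``conf_threshold`` are dropped, then class-wise greedy NMS is applied.
    Boxes are clipped to [0, input_size] when ``input_size`` is given.
    """
    if not (0 <= conf_threshold <= 1 and 0 <= nms_iou_threshold <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    if not raw_outputs:
        return []
    reg, obj, cls, grid, strides = flatten_raw_outputs(raw_outputs)
    boxes_all = decode_boxes(reg, grid, strides)
    obj_p = 1.0 / (1.0 + np.exp(-obj))
    cls_p = 1.0 / (1.0 + np.exp(-cls))
    results = []
    for n in range(reg.shape[0]):
        scores = obj_p[n][:, None] * cls_p[n]          # (A, nc)
        labels = scores.argmax(axis=1)
        best = scores[np.arange(len(labels)), labels]
        m = best >= conf_threshold
        boxes, best, labels = boxes_all[n][m], best[m], labels[m]
        if input_size is not None:
            boxes = np.clip(boxes, 0, input_size)
        kb, ks, kl = [], [], []
        for c in np.unique(labels):
            cm = labels == c
            keep = nms_greedy(boxes[cm], best[cm], nms_iou_threshold)
            kb.append(boxes[cm][keep])
            ks.append(best[cm][keep])
            kl.append(np.full(len(keep), c, dtype=np.int64))
        if kb:
            boxes = np.concatenate(kb)
            scores_k = np.concatenate(ks)
            labels_k = np.concatenate(kl)
            order = np.argsort(-scores_k, kind="stable")
            results.append(BoxSet(boxes[order], labels_k[order], scores_k[order]))
        else:
            results.append(BoxSet.empty())
    return results


# ---------------------------------------------------------------------------
# checkpoints and detection export
# ---------------------------------------------------------------------------


def save_checkpoint(model: nn.Module, path) -> None:
    """Flat parameter-path -> tensor mapping, stored as an .npz archive."""
    np.savez(path, **model.state_dict())


def load_checkpoint(model: nn.Module, path, strict: bool = False):
    """Load a (possibly partial, e.g. backbone-only) checkpoint.

    Returns ``(missing, unexpected)`` parameter-path lists.
    """
    with np.load(path) as data:
        state = {k: data[k] for k in data.files}
    return model.load_state_dict(state, strict=strict)


def detections_to_coco_json(detections: dict[int, BoxSet], path=None,
                            category_offset: int = 1) -> list[dict]:
    """Export per-image detections as COCO detection-results records
    (image_id, category_id, bbox [x, y, w, h], score)."""
    records = []
    for image_id, det in detections.items():
        for box, label, score in zip(det.boxes, det.labels, det.scores):
            x1, y1, x2, y2 = (float(v) for v in box)
            records.append({
                "image_id": int(image_id),
                "category_id": int(label) + category_offset,
                "bbox": [x1, y1, x2 - x1, y2 - y1],
                "score": float(score),
            })
    if path is not None:
        with open(path, "w") as fh:
            json.dump(records, fh)
    return records
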
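"""Box-regression and classification losses.

The IoU-family regression loss is ``L(B, B_gt) = 1 - IoU(B, B_gt) + R(B, B_gt)``
with the penalty term R selecting the variant:

===========  ==============================================================
``iou``      R = 0
``giou``     R = |C \\ (A u B)| / |C|, C the smallest enclosing box
``diou``     R = rho^2(centers) / c^2, c the enclosing-box diagonal
``ciou``     R = diou penalty + alpha*v,
             v = (4/pi^2) (arctan(w_gt/h_gt) - arctan(w/h))^2,
             alpha = v / ((1 - IoU) + v)
===========  ==============================================================

The Focal-IoU loss re-weights the plain IoU loss by the overlap quality,

    L_FocalIoU = IoU^gamma * (1 - IoU),        gamma = 0.5 by default,

which vanishes both for perfect boxes (IoU = 1) and for hopeless,
non-overlapping pairs (IoU = 0), concentrating the gradient signal on
predictions that can still be improved.  Its maximum over IoU in [0, 1]
sits at IoU = gamma / (gamma + 1).

The Focal classification loss ``-alpha_t (1 - p_t)^gamma log(p_t)``
down-weights easily classified (mostly background) samples.

Public functions take plain numpy box arrays ``(..., 4)`` in
(x_min, y_min, x_max, y_max) order and broadcast elementwise over leading
dimensions.  The ``*_t`` variants operate on autodiff tensors and are the
ones the trainer differentiates through.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .model_core import LossConfig

_EPS = 1e-10


class NaNLossError(FloatingPointError):
    """A loss component became non-finite; the message names it."""


# ---------------------------------------------------------------------------
# numpy (analytic) API
# ---------------------------------------------------------------------------


def _areas(b: np.ndarray) -> np.ndarray:
    return (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])


def iou(box_a, box_b) -> np.ndarray:
    """Elementwise intersection-over-union of two broadcastable box arrays.

    Degenerate (zero- or negative-area) boxes yield IoU 0 with a warning,
    never NaN.
    """
    a = np.asarray(box_a, dtype=np.float64)
    b = np.asarray(box_b, dtype=np.float64)
    area_a, area_b = _areas(a), _areas(b)
    degenerate = (area_a <= 0) | (area_b <= 0)
    if np.any(degenerate):
        warnings.warn("degenerate (zero-area) box in IoU; treating overlap as 0",
                      RuntimeWarning, stacklevel=2)
    iw = np.clip(np.minimum(a[..., 2], b[..., 2]) - np.maximum(a[..., 0], b[..., 0]), 0, None)
    ih = np.clip(np.minimum(a[..., 3], b[..., 3]) - np.maximum(a[..., 1], b[..., 1]), 0, None)
    inter = iw * ih
    union = area_a + area_b - inter
    out = np.where(degenerate | (union <= 0), 0.0, inter / np.maximum(union, _EPS))
    return out if out.ndim else float(out)


def iou_family_loss(box, box_gt, variant: str = "iou") -> np.ndarray:
    """``1 - IoU + R`` with the variant's penalty term R (see module docs)."""
    a = np.asarray(box, dtype=np.float64)
    b = np.asarray(box_gt, dtype=np.float64)
    u = np.asarray(iou(a, b), dtype=np.float64)
    if variant == "iou":
        r = 0.0
    elif variant == "giou":
        iw = np.clip(np.minimum(a[..., 2], b[..., 2]) - np.maximum(a[..., 0], b[..., 0]), 0, None)
        ih = np.clip(np.minimum(a[..., 3], b[..., 3]) - np.maximum(a[..., 1], b[..., 1]), 0, None)
        union = _areas(a) + _areas(b) - iw * ih
        cw = np.maximum(a[..., 2], b[..., 2]) - np.minimum(a[..., 0], b[..., 0])
        ch = np.maximum(a[..., 3], b[..., 3]) - np.minimum(a[..., 1], b[..., 1])
        enclosing = cw * ch
        r = (enclosing - union) / np.maximum(enclosing, _EPS)
    elif variant in ("diou", "ciou"):
        cxa, cya = (a[..., 0] + a[..., 2]) / 2, (a[..., 1] + a[..., 3]) / 2
        cxb, cyb = (b[..., 0] + b[..., 2]) / 2, (b[..., 1] + b[..., 3]) / 2
        rho2 = (cxa - cxb) ** 2 + (cya - cyb) ** 2
        cw = np.maximum(a[..., 2], b[..., 2]) - np.minimum(a[..., 0], b[..., 0])
        ch = np.maximum(a[..., 3], b[..., 3]) - np.minimum(a[..., 1], b[..., 1])
        c2 = cw ** 2 + ch ** 2
        r = rho2 / np.maximum(c2, _EPS)
        if variant == "ciou":
            wa = np.maximum(a[..., 2] - a[..., 0], _EPS)
            ha = np.maximum(a[..., 3] - a[..., 1], _EPS)
            wb = np.maximum(b[..., 2] - b[..., 0], _EPS)
            hb = np.maximum(b[..., 3] - b[..., 1], _EPS)
            v = (4.0 / np.pi ** 2) * (np.arctan(wb / hb) - np.arctan(wa / ha)) ** 2
            alpha = v / np.maximum((1.0 - u) + v, _EPS)
            r = r + alpha * v
    else:
        raise ValueError(f"unknown IoU loss variant: {variant!r}")
    out = 1.0 - u + r
    return out if np.ndim(out) else float(out)


def focal_iou_loss(box, box_gt, gamma: float = 0.5) -> np.ndarray:
    """``IoU^gamma * (1 - IoU)`` (the plain IoU loss re-weighted by quality)."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    u = np.asarray(iou(box, box_gt), dtype=np.float64)
    out = np.where(u > 0, u ** gamma, 0.0 if gamma > 0 else 1.0) * (1.0 - u)
    return out if out.ndim else float(out)


def focal_iou_of(u, gamma: float = 0.5):
    """Focal-IoU loss as a direct function of an IoU value in [0, 1]."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    u = np.asarray(u, dtype=np.float64)
    out = np.where(u > 0, u ** gamma, 0.0 if gamma > 0 else 1.0) * (1.0 - u)
    return out if out.ndim else float(out)


def focal_cls_loss(p_t, alpha_t: float = 0.25, gamma: float = 2.0) -> np.ndarray:
    """Focal classification loss ``-alpha_t (1 - p_t)^gamma log(p_t)``."""
    if not 0.0 <= gamma <= 5.0:
        raise ValueError("gamma must lie in [0, 5]")
    p = np.asarray(p_t, dtype=np.float64)
    if np.any(p <= 0):
        warnings.warn("p_t <= 0 clamped to machine-epsilon floor", RuntimeWarning, stacklevel=2)
        p = np.maximum(p, np.finfo(np.float64).eps)
    out = -alpha_t * (1.0 - p) ** gamma * np.log(p)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# loss bundle
# ---------------------------------------------------------------------------


@dataclass
class LossBundle:
    """Per-batch loss components with the standard 5 / 1 / 1 weighting."""

    box_loss: float
    cls_loss: float
    obj_loss: float
    weights: LossConfig = None

    def __post_init__(self):
        if self.weights is None:
            self.weights = LossConfig()
        for name in ("box_loss", "cls_loss", "obj_loss"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise NaNLossError(f"{name} is not finite: {v}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> float:
        w = self.weights
        return w.box_weight * self.box_loss + w.cls_weight * self.cls_loss + w.obj_weight * self.obj_loss

    def as_dict(self) -> dict:
        return {"box": self.box_loss, "cls": self.cls_loss, "obj": self.obj_loss,
                "total": self.total}


# ---------------------------------------------------------------------------
# differentiable (tensor) API used by the trainer
# ---------------------------------------------------------------------------


def iou_t(pred: nn.Tensor, gt: np.ndarray) -> nn.Tensor:
    """Differentiable pairwise IoU of predicted boxes vs fixed targets (M, 4)."""
    gt = np.asarray(gt, dtype=np.float32)
    iw = (nn.minimum(pred[:, 2], gt[:, 2]) - nn.maximum(pred[:, 0], gt[:, 0])).clip(0.0, None)
    ih = (nn.minimum(pred[:, 3], gt[:, 3]) - nn.maximum(pred[:, 1], gt[:, 1])).clip(0.0, None)
    inter = iw * ih
    area_p = (pred[:, 2] - pred[:, 0]).clip(0.0, None) * (pred[:, 3] - pred[:, 1]).clip(0.0, None)
    area_g = (gt[:, 2] - gt[:, 0]) * (gt[:, 3] - gt[:, 1])
    union = area_p + area_g - inter
    return inter / (union + _EPS)


def box_loss_t(pred: nn.Tensor, gt: np.ndarray, variant: str = "iou",
               gamma: float = 0.5) -> nn.Tensor:
    """Differentiable per-pair box loss; mean over the M pairs.

    ``focal_iou`` uses an epsilon floor inside ``IoU^gamma`` so the gradient
    stays finite at IoU = 0 (the analytic value there is 0 either way).
    """
    gt = np.asarray(gt, dtype=np.float32)
    u = iou_t(pred, gt)
    if variant == "iou":
        loss = 1.0 - u
    elif variant == "focal_iou":
        loss = (u.clip(1e-7, 1.0) ** gamma) * (1.0 - u)
    elif variant == "giou":
        iw = (nn.minimum(pred[:, 2], gt[:, 2]) - nn.maximum(pred[:, 0], gt[:, 0])).clip(0.0, None)
        ih = (nn.minimum(pred[:, 3], gt[:, 3]) - nn.maximum(pred[:, 1], gt[:, 1])).clip(0.0, None)
        area_p = (pred[:, 2] - pred[:, 0]).clip(0.0, None) * (pred[:, 3] - pred[:, 1]).clip(0.0, None)
        area_g = (gt[:, 2] - gt[:, 0]) * (gt[:, 3] - gt[:, 1])
        union = area_p + area_g - iw * ih
        cw = nn.maximum(pred[:, 2], gt[:, 2]) - nn.minimum(pred[:, 0], gt[:, 0])
        ch = nn.maximum(pred[:, 3], gt[:, 3]) - nn.minimum(pred[:, 1], gt[:, 1])
        enclosing = cw * ch
        loss = 1.0 - u + (enclosing - union) / (enclosing + _EPS)
    elif variant in ("diou", "ciou"):
        cxp = (pred[:, 0] + pred[:, 2]) * 0.5
        cyp = (pred[:, 1] + pred[:, 3]) * 0.5
        cxg = (gt[:, 0] + gt[:, 2]) * 0.5
        cyg = (gt[:, 1] + gt[:, 3]) * 0.5
        rho2 = (cxp - cxg) ** 2.0 + (cyp - cyg) ** 2.0
        cw = nn.maximum(pred[:, 2], gt[:, 2]) - nn.minimum(pred[:, 0], gt[:, 0])
        ch = nn.maximum(pred[:, 3], gt[:, 3]) - nn.minimum(pred[:, 1], gt[:, 1])
        c2 = cw ** 2.0 + ch ** 2.0
        loss = 1.0 - u + rho2 / (c2 + _EPS)
        if variant == "ciou":
            wp = (pred[:, 2] - pred[:, 0]).clip(_EPS, None)
            hp = (pred[:, 3] - pred[:, 1]).clip(_EPS, None)
            wg = np.maximum(gt[:, 2] - gt[:, 0], _EPS)
            hg = np.maximum(gt[:, 3] - gt[:, 1], _EPS)
            v = (4.0 / np.pi ** 2) * ((wp / hp).arctan() - np.arctan(wg / hg)) ** 2.0
            alpha = (v / ((1.0 - u) + v + _EPS)).detach()  # alpha is a constant weight
            loss = loss + alpha * v
    else:
        raise ValueError(f"unknown IoU loss variant: {variant!r}")
    return loss.mean()


def bce_with_logits_t(logits: nn.Tensor, targets: np.ndarray,
                      reduction: str = "mean") -> nn.Tensor:
    """Numerically stable binary cross-entropy on raw logits.

    Uses the identity BCE(x, t) = max(x, 0) - x*t + log(1 + exp(-|x|)).
    """
    t = np.asarray(targets, dtype=np.float32)
    absx = nn.maximum(logits, -logits)
    loss = nn.maximum(logits, 0.0) - logits * t + (1.0 + (-absx).exp()).log()
    return loss.sum() if reduction == "sum" else loss.mean()


def focal_cls_loss_t(logits: nn.Tensor, targets: np.ndarray,
                     alpha_t: float = 0.25, gamma: float = 2.0) -> nn.Tensor:
    """Differentiable focal loss on raw logits (binary, per element)."""
    if not 0.0 <= gamma <= 5.0:
        raise ValueError("gamma must lie in [0, 5]")
    t = np.asarray(targets, dtype=np.float32)
    p = logits.sigmoid().clip(1e-7, 1.0 - 1e-7)
    p_t = p * t + (1.0 - p) * (1.0 - t)
    alpha = alpha_t * t + (1.0 - alpha_t) * (1.0 - t)
    return (-(alpha) * (1.0 - p_t) ** gamma * p_t.log()).mean()
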
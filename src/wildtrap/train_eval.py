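"""Training loop, dataset splitting, COCO-protocol mAP and visual diagnostics.

Training follows the usual recipe for this detector family: SimOTA dynamic
label assignment (center-prior candidates, per-object dynamic top-k by a
classification + IoU cost), a weighted sum of box / objectness / class
losses (weights 5 / 1 / 1), cosine-annealed learning rate, and a strong
augmentation phase (mosaic, horizontal flip, HSV jitter) that is switched
off for the final epochs.  Evaluation uses COCO-style average precision
with 101-point interpolation at IoU thresholds 0.50:0.05:0.95.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import losses as L
from . import nn
from .losses import NaNLossError
from .model_core import (
    BoxSet,
    DetectorModel,
    STRIDES,
    box_iou_matrix,
    decode_predictions,
)
from .synthetic_data import Dataset

# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

OPTIMIZERS = ("sgd_momentum", "adam")


@dataclass
class TrainSchedule:
    epochs: int = 300
    lr_init: float = 0.01
    lr_min: float = 0.0001
    momentum: float = 0.9
    aug_epochs: int = 285          # strong augmentation on, then off
    optimizer: str = "sgd_momentum"
    weight_decay: float = 5e-4
    batch_size: int = 8
    warmup_iters: int = 0          # linear lr ramp over the first iterations

    def validate(self) -> "TrainSchedule":
        if self.aug_epochs > self.epochs:
            raise ValueError("aug_epochs must be <= epochs")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {OPTIMIZERS}")
        return self


def cosine_lr(epoch: int, schedule: TrainSchedule) -> float:
    """Cosine-annealed learning rate; lr(0) = lr_init, lr(epochs) = lr_min."""
    if not 0 <= epoch <= schedule.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {schedule.epochs}]")
    return schedule.lr_min + 0.5 * (schedule.lr_init - schedule.lr_min) * (
        1.0 + math.cos(math.pi * epoch / schedule.epochs))


def split_dataset(items, ratios=(8, 1, 1), seed: int = 0):
    """Uniform random disjoint partition with sizes proportional to ratios
    (remainders go to the first, training, split); deterministic per seed."""
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    items = list(items)
    n = len(items)
    perm = np.random.default_rng(seed).permutation(n)
    total = sum(ratios)
    n_val = n * ratios[1] // total
    n_test = n * ratios[2] // total
    n_train = n - n_val - n_test
    idx = [perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]]
    return tuple([items[i] for i in part] for part in idx)


# ---------------------------------------------------------------------------
# COCO-protocol mAP
# ---------------------------------------------------------------------------

COCO_THRESHOLDS = tuple(np.round(np.arange(0.5, 1.0, 0.05), 2))
RECALL_POINTS = np.linspace(0, 1, 101)


@dataclass
class EvalResult:
    map50: float
    map5095: float
    per_class_ap: list = field(default_factory=list)


def _class_ap(dets, gts, iou_thr: float) -> float | None:
    """AP of one class at one IoU threshold, 101-point interpolation.

    ``dets``: list of (image_id, score, box); ``gts``: image_id -> (G, 4).
    Classes with no ground truth are excluded from the mean (COCO protocol:
    their AP is undefined), signalled by returning None.
    """
    n_gt = sum(len(g) for g in gts.values())
    if n_gt == 0:
        return None
    if not dets:
        return 0.0
    order = sorted(range(len(dets)), key=lambda i: -dets[i][1])
    matched = {img: np.zeros(len(g), dtype=bool) for img, g in gts.items()}
    tp = np.zeros(len(order))
    for rank, i in enumerate(order):
        img, _, box = dets[i]
        g = gts.get(img)
        if g is None or len(g) == 0:
            continue
        ious = box_iou_matrix(box.reshape(1, 4), g)[0]
        ious[matched[img]] = -1.0          # each gt matches at most one det
        j = int(np.argmax(ious))
        if ious[j] >= iou_thr:
            matched[img][j] = True
            tp[rank] = 1.0
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(1.0 - tp)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    # precision envelope, then 101-point average
    for i in range(len(precision) - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    ap = 0.0
    for r in RECALL_POINTS:
        idx = np.searchsorted(recall, r, side="left")
        ap += precision[idx] if idx < len(precision) else 0.0
    return ap / len(RECALL_POINTS)


def evaluate_map(detections: list[BoxSet], ground_truth: list[BoxSet],
                 iou_thresholds=COCO_THRESHOLDS, num_classes: int | None = None) -> EvalResult:
    """COCO-protocol mAP over parallel per-image detection / ground-truth lists."""
    if len(detections) != len(ground_truth):
        raise ValueError("detections and ground_truth must be parallel per-image lists")
    if num_classes is None:
        labels = [b.labels for b in detections + ground_truth if len(b)]
        num_classes = int(max((lab.max() for lab in labels), default=0)) + 1
    per_thr_ap = {}
    for thr in iou_thresholds:
        aps = []
        for c in range(num_classes):
            dets = []
            gts = {}
            for img, (d, g) in enumerate(zip(detections, ground_truth)):
                sel = d.labels == c
                for box, score in zip(d.boxes[sel], d.scores[sel] if d.scores is not None else np.ones(sel.sum())):
                    dets.append((img, float(score), box))
                gsel = g.labels == c
                if gsel.any():
                    gts[img] = g.boxes[gsel]
            ap = _class_ap(dets, gts, thr)
            if ap is not None:
                aps.append(ap)
        per_thr_ap[thr] = (float(np.mean(aps)) if aps else 0.0, aps)
    anchor = 0.5 if 0.5 in per_thr_ap else iou_thresholds[0]
    map5095 = float(np.mean([per_thr_ap[t][0] for t in iou_thresholds]))
    return EvalResult(per_thr_ap[anchor][0], map5095, per_thr_ap[anchor][1])


# ---------------------------------------------------------------------------
# SimOTA label assignment
# ---------------------------------------------------------------------------


def simota_assign(pred_boxes: np.ndarray, obj_logits: np.ndarray, cls_logits: np.ndarray,
                  gt_boxes: np.ndarray, gt_labels: np.ndarray,
                  centers: np.ndarray, strides: np.ndarray,
                  center_radius: float = 2.5, cls_cost_weight: float = 1.0,
                  iou_cost_weight: float = 3.0, topk: int = 10):
    """Dynamic top-k assignment of ground-truth boxes to head locations.

    Returns ``(fg_idx, matched_gt)``: indices of foreground locations and,
    parallel to them, the index of the ground-truth box each one regresses.
    """
    a = len(centers)
    g = len(gt_boxes)
    if g == 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    cx, cy = centers[:, 0], centers[:, 1]
    in_box = ((cx[None] >= gt_boxes[:, 0, None]) & (cx[None] <= gt_boxes[:, 2, None])
              & (cy[None] >= gt_boxes[:, 1, None]) & (cy[None] <= gt_boxes[:, 3, None]))
    gcx = (gt_boxes[:, 0] + gt_boxes[:, 2]) / 2
    gcy = (gt_boxes[:, 1] + gt_boxes[:, 3]) / 2
    r = center_radius * strides[None]
    in_center = ((np.abs(cx[None] - gcx[:, None]) <= r)
                 & (np.abs(cy[None] - gcy[:, None]) <= r))
    cand = (in_box | in_center).any(axis=0)
    cand_idx = np.nonzero(cand)[0]
    if len(cand_idx) == 0:
        # fall back to the location nearest each gt center
        d2 = (cx[None] - gcx[:, None]) ** 2 + (cy[None] - gcy[:, None]) ** 2
        fg = np.argmin(d2, axis=1).astype(np.int64)
        return fg, np.arange(g, dtype=np.int64)
    ious = box_iou_matrix(gt_boxes, pred_boxes[cand_idx])          # (G, C)
    obj_p = 1.0 / (1.0 + np.exp(-obj_logits[cand_idx]))
    cls_p = 1.0 / (1.0 + np.exp(-cls_logits[cand_idx]))
    joint = np.clip(cls_p * obj_p[:, None], 1e-8, 1 - 1e-8)        # (C, nc)
    bce_all = -np.log(1.0 - joint).sum(axis=1)                     # sum over classes of BCE target 0
    pos = -np.log(joint)                                            # target-1 term per class
    neg = -np.log(1.0 - joint)
    cls_cost = bce_all[None, :] - neg[:, gt_labels].T + pos[:, gt_labels].T
    iou_cost = -np.log(ious + 1e-8)
    both = (in_box & in_center)[:, cand_idx]
    cost = cls_cost_weight * cls_cost + iou_cost_weight * iou_cost + 1e5 * (~both)
    # dynamic k per gt from the total attainable IoU mass
    k_iou = np.sort(ious, axis=1)[:, ::-1][:, :min(topk, ious.shape[1])]
    dyn_k = np.clip(k_iou.sum(axis=1).astype(int), 1, ious.shape[1])
    assign = np.full(len(cand_idx), -1, dtype=np.int64)
    assign_cost = np.full(len(cand_idx), np.inf)
    for gi in range(g):
        order = np.argsort(cost[gi])[: dyn_k[gi]]
        for ci in order:
            if cost[gi, ci] < assign_cost[ci]:
                assign_cost[ci] = cost[gi, ci]
                assign[ci] = gi
    sel = assign >= 0
    return cand_idx[sel], assign[sel]


# ---------------------------------------------------------------------------
# loss computation on raw head outputs
# ---------------------------------------------------------------------------


def _flatten_levels(raw_outputs):
    """Differentiable flatten of per-level raw maps to (N, A, *) tensors."""
    regs, objs, clss = [], [], []
    centers, strides = [], []
    for (reg, obj, cls), s in zip(raw_outputs, STRIDES):
        n, _, h, w = reg.shape
        regs.append(reg.reshape(n, 4, h * w).transpose(0, 2, 1))
        objs.append(obj.reshape(n, h * w))
        clss.append(cls.reshape(n, cls.shape[1], h * w).transpose(0, 2, 1))
        ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        centers.append(np.stack([(xs.reshape(-1) + 0.5) * s, (ys.reshape(-1) + 0.5) * s], axis=1))
        strides.append(np.full(h * w, s, dtype=np.float32))
    return (nn.concat(regs, axis=1), nn.concat(objs, axis=1), nn.concat(clss, axis=1),
            np.concatenate(centers).astype(np.float32), np.concatenate(strides))


def compute_loss(raw_outputs, targets: list[BoxSet], config):
    """SimOTA-assigned detection loss; returns (total Tensor, LossBundle, n_fg)."""
    reg_t, obj_t, cls_t, centers, strides = _flatten_levels(raw_outputs)
    n, a, nc = cls_t.shape
    grid = np.stack([centers[:, 0] / strides - 0.5, centers[:, 1] / strides - 0.5], axis=1)
    reg_np = reg_t.data
    pred_boxes_np = np.stack([
        (grid[:, 0] + reg_np[..., 0]) * strides - np.exp(reg_np[..., 2]) * strides / 2,
        (grid[:, 1] + reg_np[..., 1]) * strides - np.exp(reg_np[..., 3]) * strides / 2,
        (grid[:, 0] + reg_np[..., 0]) * strides + np.exp(reg_np[..., 2]) * strides / 2,
        (grid[:, 1] + reg_np[..., 1]) * strides + np.exp(reg_np[..., 3]) * strides / 2,
    ], axis=-1)

    obj_target = np.zeros((n, a), dtype=np.float32)
    img_idx, anchor_idx, gt_box_list, gt_cls_list, gt_iou_list = [], [], [], [], []
    for i, gt in enumerate(targets):
        fg, matched = simota_assign(pred_boxes_np[i], obj_t.data[i], cls_t.data[i],
                                    gt.boxes, gt.labels, centers, strides)
        if len(fg) == 0:
            continue
        obj_target[i, fg] = 1.0
        img_idx.append(np.full(len(fg), i))
        anchor_idx.append(fg)
        gt_box_list.append(gt.boxes[matched])
        gt_cls_list.append(gt.labels[matched])
        pair_iou = box_iou_matrix(pred_boxes_np[i, fg], gt.boxes[matched]).diagonal()
        gt_iou_list.append(pair_iou)

    # YOLOX normalization: every component is a sum divided by the number of
    # foreground assignments, so positive-sample gradients keep their weight
    n_fg_total = max(int(obj_target.sum()), 1)
    obj_loss = L.bce_with_logits_t(obj_t, obj_target, reduction="sum") * (1.0 / n_fg_total)
    if img_idx:
        ii = np.concatenate(img_idx)
        ai = np.concatenate(anchor_idx)
        gt_boxes = np.concatenate(gt_box_list)
        gt_cls = np.concatenate(gt_cls_list)
        m = len(ii)
        reg_fg = reg_t[ii, ai]                                  # (M, 4) differentiable
        gx, gs = grid[ai], strides[ai]
        cx = (gx[:, 0] + reg_fg[:, 0]) * gs
        cy = (gx[:, 1] + reg_fg[:, 1]) * gs
        w = reg_fg[:, 2].clip(-8.0, 8.0).exp() * gs
        h = reg_fg[:, 3].clip(-8.0, 8.0).exp() * gs
        pred_fg = nn.concat([(cx - w * 0.5).reshape(m, 1), (cy - h * 0.5).reshape(m, 1),
                             (cx + w * 0.5).reshape(m, 1), (cy + h * 0.5).reshape(m, 1)], axis=1)
        box_loss = L.box_loss_t(pred_fg, gt_boxes, config.box_loss, config.focal_gamma)
        # soft classification target: one-hot scaled by the current box IoU,
        # so the obj*cls score learns to rank detections by box quality
        onehot = np.zeros((m, nc), dtype=np.float32)
        onehot[np.arange(m), gt_cls] = np.concatenate(gt_iou_list).astype(np.float32)
        cls_loss = L.bce_with_logits_t(cls_t[ii, ai], onehot, reduction="sum") * (1.0 / n_fg_total)
        n_fg = m
    else:
        box_loss = nn.Tensor(0.0)
        cls_loss = nn.Tensor(0.0)
        n_fg = 0

    w_cfg = config.loss
    total = w_cfg.box_weight * box_loss + w_cfg.cls_weight * cls_loss + w_cfg.obj_weight * obj_loss
    bundle = L.LossBundle(float(box_loss.data), float(cls_loss.data), float(obj_loss.data), w_cfg)
    return total, bundle, n_fg


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _resize_image(img: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of an (H, W, 3) float image to (size, size, 3)."""
    from .nn import _interp_matrix

    ah = _interp_matrix(size, img.shape[0])
    aw = _interp_matrix(size, img.shape[1])
    out = np.matmul(np.matmul(ah, img.transpose(2, 0, 1)), aw.T)
    return out.transpose(1, 2, 0)


def _scene_to_sample(scene, size: int):
    img = scene.image.astype(np.float32) / 255.0
    boxes = scene.boxes.boxes.copy()
    labels = scene.boxes.labels.copy()
    h, w = img.shape[:2]
    if (h, w) != (size, size):
        img = _resize_image(img, size)
        boxes = boxes * np.array([size / w, size / h, size / w, size / h], dtype=np.float32)
    return img, boxes, labels


def _hflip(img, boxes):
    w = img.shape[1]
    img = img[:, ::-1].copy()
    if len(boxes):
        boxes = boxes.copy()
        x0 = w - boxes[:, 2]
        x1 = w - boxes[:, 0]
        boxes[:, 0], boxes[:, 2] = x0, x1
    return img, boxes


def _hsv_jitter(img, rng):
    gray = img.mean(axis=2, keepdims=True)
    sat = rng.uniform(0.6, 1.4)
    val = rng.uniform(0.6, 1.4)
    hue = rng.uniform(0.95, 1.05, size=3)
    return np.clip((gray + (img - gray) * sat) * val * hue, 0, 1)


def _mosaic(samples, size: int, rng):
    """Compose four (img, boxes, labels) samples into one mosaic image."""
    canvas = np.zeros((size, size, 3), dtype=np.float32)
    cx = int(rng.uniform(0.3, 0.7) * size)
    cy = int(rng.uniform(0.3, 0.7) * size)
    quads = [(0, 0, cx, cy), (cx, 0, size - cx, cy), (0, cy, cx, size - cy), (cx, cy, size - cx, size - cy)]
    out_boxes, out_labels = [], []
    for (ox, oy, qw, qh), (img, boxes, labels) in zip(quads, samples):
        if qw < 2 or qh < 2:
            continue
        h, w = img.shape[:2]
        patch = _resize_image(img, max(qw, qh))[:qh, :qw]
        canvas[oy : oy + qh, ox : ox + qw] = patch
        if len(boxes):
            s = max(qw, qh)
            b = boxes * np.array([s / w, s / h, s / w, s / h], dtype=np.float32)
            b[:, [0, 2]] = np.clip(b[:, [0, 2]], 0, qw) + ox
            b[:, [1, 3]] = np.clip(b[:, [1, 3]], 0, qh) + oy
            keep = (b[:, 2] - b[:, 0] >= 2) & (b[:, 3] - b[:, 1] >= 2)
            out_boxes.append(b[keep])
            out_labels.append(labels[keep])
    boxes = np.concatenate(out_boxes) if out_boxes else np.zeros((0, 4), dtype=np.float32)
    labels = np.concatenate(out_labels) if out_labels else np.zeros(0, dtype=np.int64)
    return canvas, boxes, labels


def make_batch(dataset: Dataset, indices, size: int, augment: bool, rng):
    """Assemble a training batch; with ``augment`` applies mosaic (p=0.5),
    horizontal flip (p=0.5) and HSV jitter, otherwise returns the plain
    (deterministically resized) source images."""
    imgs, gts = [], []
    for idx in indices:
        if augment and rng.random() < 0.5 and len(dataset) >= 4:
            others = rng.integers(0, len(dataset), size=3)
            samples = [_scene_to_sample(dataset.scenes[j], size) for j in [idx, *others]]
            img, boxes, labels = _mosaic(samples, size, rng)
        else:
            img, boxes, labels = _scene_to_sample(dataset.scenes[idx], size)
        if augment:
            if rng.random() < 0.5:
                img, boxes = _hflip(img, boxes)
            img = _hsv_jitter(img, rng)
        imgs.append(img.transpose(2, 0, 1))
        gts.append(BoxSet(boxes, labels) if len(boxes) else BoxSet.empty())
    return np.stack(imgs).astype(np.float32), gts


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train(model: DetectorModel, dataset: Dataset, schedule: TrainSchedule,
          seed: int = 0, input_size: int | None = None, max_iters: int | None = None,
          eval_every: int | None = None, target_map50: float | None = None,
          log_path=None, verbose: bool = False):
    """Train ``model`` on ``dataset``; returns (model, log).

    The log is a list of per-iteration records (epoch, iter, lr and loss
    components).  Strong augmentation runs for the first ``aug_epochs``
    epochs only.  With ``eval_every``/``target_map50`` set, training stops
    early once the train-set mAP@0.5 reaches the target (checked on the
    undistorted images); ``max_iters`` caps the total iteration count.
    """
    schedule.validate()
    if len(dataset) == 0:
        raise ValueError("empty training set")
    size = input_size or model.config.input_size
    rng = np.random.default_rng(seed)
    params = list(model.parameters())
    if schedule.optimizer == "adam":
        opt = nn.Adam(params, lr=schedule.lr_init, weight_decay=schedule.weight_decay)
    else:
        opt = nn.SGD(params, lr=schedule.lr_init, momentum=schedule.momentum,
                     weight_decay=schedule.weight_decay)
    log = []
    model.train()
    it = 0
    bs = schedule.batch_size
    stop = False
    for epoch in range(schedule.epochs):
        lr = cosine_lr(epoch, schedule)
        order = rng.permutation(len(dataset))
        augment = epoch < schedule.aug_epochs
        for start in range(0, len(order), bs):
            if schedule.warmup_iters and it < schedule.warmup_iters:
                opt.lr = lr * (it + 1) / schedule.warmup_iters
            else:
                opt.lr = lr
            idxs = order[start : start + bs]
            images, gts = make_batch(dataset, idxs, size, augment, rng)
            raw = model(images)
            total, bundle, n_fg = compute_loss(raw, gts, model.config)
            if not np.isfinite(bundle.total):
                bad = [k for k, v in bundle.as_dict().items() if not np.isfinite(v)]
                raise NaNLossError(f"non-finite loss component(s): {bad} at iter {it}")
            opt.zero_grad()
            total.backward()
            opt.step()
            rec = {"epoch": epoch, "iter": it, "lr": opt.lr, "n_fg": int(n_fg), **bundle.as_dict()}
            log.append(rec)
            if verbose and it % 10 == 0:
                print(f"iter {it:5d} epoch {epoch:3d} lr {lr:.5f} "
                      f"total {bundle.total:.3f} box {bundle.box_loss:.3f} "
                      f"obj {bundle.obj_loss:.3f} cls {bundle.cls_loss:.3f}")
            it += 1
            if eval_every and target_map50 and it % eval_every == 0:
                res = evaluate_model(model, dataset, input_size=size)
                log.append({"iter": it, "map50": res.map50, "map5095": res.map5095})
                if verbose:
                    print(f"iter {it:5d} train mAP@0.5 {res.map50:.3f}")
                model.train()
                if res.map50 >= target_map50:
                    stop = True
            if max_iters is not None and it >= max_iters:
                stop = True
            if stop:
                break
        if stop:
            break
    model.eval()
    if log_path is not None:
        with open(log_path, "w") as fh:
            for rec in log:
                fh.write(json.dumps(rec) + "\n")
    return model, log


def evaluate_model(model: DetectorModel, dataset: Dataset, input_size: int | None = None,
                   conf_threshold: float = 0.01, nms_iou_threshold: float = 0.65,
                   batch_size: int = 8) -> EvalResult:
    """Run inference over a dataset and score it with COCO-protocol mAP."""
    size = input_size or model.config.input_size
    was_training = model.training
    model.eval()
    dets, gts = [], []
    for start in range(0, len(dataset), batch_size):
        scenes = dataset.scenes[start : start + batch_size]
        imgs, boxes = zip(*[_scene_to_sample(s, size)[:2] for s in scenes])
        labels = [s.boxes.labels for s in scenes]
        x = np.stack([im.transpose(2, 0, 1) for im in imgs]).astype(np.float32)
        with nn.no_grad():
            raw = model(x)
        dets.extend(decode_predictions(raw, conf_threshold, nms_iou_threshold, input_size=size))
        gts.extend(BoxSet(b, l) if len(b) else BoxSet.empty() for b, l in zip(boxes, labels))
    if was_training:
        model.train()
    return evaluate_map(dets, gts, num_classes=model.config.num_classes)


def overfit_smoke(data_seed: int = 3, model_seed: int = 0, train_seed: int = 0,
                  n_images: int = 20, width: float = 0.25, input_size: int = 256,
                  max_iters: int = 300, target_map50: float = 0.9,
                  verbose: bool = False):
    """End-to-end pipeline check: overfit a reduced detector on a small
    synthetic set until the train-set mAP@0.5 reaches ``target_map50``.

    Uses the baseline architecture at ``width`` with the Adam optimizer
    (cosine 1e-3 -> 1e-4, batch 8, strong augmentation off) and evaluates
    on the undistorted training images every 25 iterations.  Returns
    ``(EvalResult, iterations_run, log)``.
    """
    from .model_core import ModelConfig, build_model
    from .synthetic_data import SceneConfig, generate_dataset

    cfg = ModelConfig.baseline(width_multiple=width, input_size=input_size)
    model = build_model(cfg, seed=model_seed)
    dataset = generate_dataset(SceneConfig(image_size=input_size, seed=data_seed), n_images)
    # cosine horizon 1.5x the iteration budget, so the lr is still useful
    # if early stopping does not trigger
    iters_per_epoch = -(-n_images // 8)
    schedule = TrainSchedule(epochs=max(1, 3 * max_iters // (2 * iters_per_epoch)),
                             lr_init=1e-3, lr_min=1e-4, optimizer="adam",
                             aug_epochs=0, batch_size=8, weight_decay=0.0,
                             warmup_iters=15)
    model, log = train(model, dataset, schedule, seed=train_seed, input_size=input_size,
                       max_iters=max_iters, eval_every=25, target_map50=target_map50,
                       verbose=verbose)
    iters = sum(1 for r in log if "total" in r)
    return evaluate_model(model, dataset, input_size=input_size), iters, log


# ---------------------------------------------------------------------------
# visual diagnostics
# ---------------------------------------------------------------------------

_PALETTE = [(230, 60, 60), (60, 180, 75), (255, 225, 25), (67, 99, 216), (245, 130, 49),
            (145, 30, 180), (70, 240, 240), (240, 50, 230), (188, 246, 12)]


def render_detections(image: np.ndarray, boxes: BoxSet,
                      class_names: list[str] | None = None) -> np.ndarray:
    """Draw labeled detection boxes on a copy of ``image`` (H, W, 3 uint8)."""
    from PIL import Image, ImageDraw

    img = Image.fromarray(np.ascontiguousarray(image))
    if len(boxes) == 0:
        return np.asarray(img)
    draw = ImageDraw.Draw(img)
    for box, label, score in zip(boxes.boxes, boxes.labels,
                                 boxes.scores if boxes.scores is not None else [None] * len(boxes)):
        color = _PALETTE[int(label) % len(_PALETTE)]
        draw.rectangle([float(box[0]), float(box[1]), float(box[2]), float(box[3])],
                       outline=color, width=2)
        name = class_names[label] if class_names else f"class_{label}"
        text = f"{name} {score:.2f}" if score is not None else name
        draw.text((float(box[0]) + 2, max(float(box[1]) - 10, 0)), text, fill=color)
    return np.asarray(img)


def activation_heatmap(model: DetectorModel, image: np.ndarray,
                       input_size: int | None = None) -> np.ndarray:
    """Gradient-weighted class-activation map on the last neck level.

    The map is normalized to [0, 1] and resized to the input's spatial
    size; a network with an all-zero head yields a uniform (flat) map.
    """
    size = input_size or model.config.input_size
    img = image.astype(np.float32) / 255.0
    h0, w0 = img.shape[:2]
    if (h0, w0) != (size, size):
        img = _resize_image(img, size)
    x = nn.Tensor(img.transpose(2, 0, 1)[None])
    was_training = model.training
    model.eval()
    feats = model.extractor(x)
    feats = model.neck(feats)
    target = feats[-1]                     # last (stride-32) neck level
    heads = feats if model.dyhead is None else model.dyhead(feats)
    raw = model.head(heads)
    score = None
    for reg, obj, cls in raw:
        s = (obj.sigmoid() * cls.sigmoid().mean(axis=1, keepdims=True)).sum()
        score = s if score is None else score + s
    score.backward()
    if was_training:
        model.train()
    grad = target.grad
    if grad is None or not np.any(grad):
        return np.zeros((h0, w0), dtype=np.float32)
    weights = grad.mean(axis=(2, 3))[0]                     # channel importances
    cam = np.maximum((weights[:, None, None] * target.data[0]).sum(axis=0), 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()
    ah = _interp_matrix_local(h0, cam.shape[0])
    aw = _interp_matrix_local(w0, cam.shape[1])
    return np.clip(ah @ cam @ aw.T, 0.0, 1.0).astype(np.float32)


def _interp_matrix_local(n_out, n_in):
    from .nn import _interp_matrix

    return _interp_matrix(n_out, n_in)
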
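"""Schedule, splitting, mAP protocol, training loop and diagnostics."""

import numpy as np
import pytest

from wildtrap.model_core import BoxSet, build_model
from wildtrap.synthetic_data import SceneConfig, generate_dataset
from wildtrap.train_eval import (
    NaNLossError,
    TrainSchedule,
    activation_heatmap,
    cosine_lr,
    evaluate_map,
    make_batch,
    render_detections,
    simota_assign,
    split_dataset,
    train,
)


class TestSchedule:
    def test_endpoints_and_midpoint(self):
        s = TrainSchedule()
        assert cosine_lr(0, s) == pytest.approx(0.01)
        assert cosine_lr(300, s) == pytest.approx(0.0001)
        assert cosine_lr(150, s) == pytest.approx(0.00505)

    def test_monotone_non_increasing(self):
        s = TrainSchedule()
        lrs = [cosine_lr(e, s) for e in range(0, 301)]
        assert (np.diff(lrs) <= 1e-12).all()

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            cosine_lr(301, TrainSchedule())

    def test_aug_epochs_bounded(self):
        with pytest.raises(ValueError):
            TrainSchedule(epochs=10, aug_epochs=11).validate()


class TestSplit:
    def test_paper_scale_sizes(self):
        tr, va, te = split_dataset(list(range(4000)), (8, 1, 1), seed=0)
        assert (len(tr), len(va), len(te)) == (3200, 400, 400)

    def test_partition_contract(self):
        items = [f"img_{i}" for i in range(103)]
        tr, va, te = split_dataset(items, (8, 1, 1), seed=3)
        assert sorted(tr + va + te) == sorted(items)
        assert not (set(tr) & set(va)) and not (set(va) & set(te)) and not (set(tr) & set(te))

    def test_determinism_and_seed_sensitivity(self):
        items = list(range(200))
        a = split_dataset(items, seed=5)
        b = split_dataset(items, seed=5)
        c = split_dataset(items, seed=6)
        assert a == b
        assert a != c
        assert tuple(map(len, a)) == tuple(map(len, c))


# ---------------------------------------------------------------------------
# independent brute-force mAP oracle (kept deliberately naive)
# ---------------------------------------------------------------------------


def _oracle_iou(a, b):
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua if ua > 0 else 0.0


def oracle_map(dets, gts, thresholds, num_classes):
    """Reference COCO-protocol mAP: greedy matching + 101-point interpolation,
    written from first principles with plain loops."""
    per_thr = []
    ap50_per_class = {}
    for thr in thresholds:
        aps = []
        for c in range(num_classes):
            records = []   # (score, image, box)
            total_gt = 0
            gt_of = {}
            for img, (d, g) in enumerate(zip(dets, gts)):
                for box, lab, sc in zip(d.boxes, d.labels, d.scores):
                    if lab == c:
                        records.append((float(sc), img, box))
                gt_of[img] = [box for box, lab in zip(g.boxes, g.labels) if lab == c]
                total_gt += len(gt_of[img])
            if total_gt == 0:
                continue
            records.sort(key=lambda r: -r[0])
            used = {img: [False] * len(g) for img, g in gt_of.items()}
            tps = []
            for sc, img, box in records:
                best, best_j = thr, -1
                for j, gbox in enumerate(gt_of[img]):
                    if used[img][j]:
                        continue
                    v = _oracle_iou(box, gbox)
                    if v >= best:
                        best, best_j = v, j
                if best_j >= 0:
                    used[img][best_j] = True
                    tps.append(1)
                else:
                    tps.append(0)
            ap = 0.0
            for r_i in range(101):
                r = r_i / 100
                best_p = 0.0
                tp = fp = 0
                for t in tps:
                    tp += t
                    fp += 1 - t
                    if tp / total_gt >= r:
                        best_p = max(best_p, tp / (tp + fp))
                ap += best_p / 101
            aps.append(ap)
            if thr == 0.5:
                ap50_per_class[c] = ap
        per_thr.append(sum(aps) / len(aps) if aps else 0.0)
    return per_thr[0], sum(per_thr) / len(per_thr)


def _random_scene_set(rng, n_images=6, num_classes=3):
    dets, gts = [], []
    for _ in range(n_images):
        n_gt = rng.integers(0, 5)
        gt_boxes, gt_labels = [], []
        det_boxes, det_labels, det_scores = [], [], []
        for _ in range(n_gt):
            x0, y0 = rng.uniform(0, 60, 2)
            w, h = rng.uniform(8, 30, 2)
            c = rng.integers(0, num_classes)
            gt_boxes.append([x0, y0, x0 + w, y0 + h])
            gt_labels.append(c)
            if rng.random() < 0.8:      # jittered true positive
                j = rng.uniform(-4, 4, 4)
                det_boxes.append([x0 + j[0], y0 + j[1], x0 + w + j[2], y0 + h + j[3]])
                det_labels.append(c if rng.random() < 0.9 else rng.integers(0, num_classes))
                det_scores.append(rng.uniform(0.3, 1.0))
        for _ in range(rng.integers(0, 3)):  # false positives
            x0, y0 = rng.uniform(0, 70, 2)
            w, h = rng.uniform(5, 25, 2)
            det_boxes.append([x0, y0, x0 + w, y0 + h])
            det_labels.append(rng.integers(0, num_classes))
            det_scores.append(rng.uniform(0.05, 0.9))
        gts.append(BoxSet(np.array(gt_boxes).reshape(-1, 4), np.array(gt_labels, dtype=int))
                   if gt_boxes else BoxSet.empty())
        dets.append(BoxSet(np.array(det_boxes).reshape(-1, 4), np.array(det_labels, dtype=int),
                           np.array(det_scores)) if det_boxes else BoxSet.empty())
    return dets, gts


class TestEvaluateMap:
    def test_perfect_detector_scores_one(self):
        gt = BoxSet(np.array([[5, 5, 20, 20], [30, 30, 50, 60]]), np.array([0, 1]))
        det = BoxSet(gt.boxes.copy(), gt.labels.copy(), np.array([1.0, 1.0]))
        res = evaluate_map([det], [gt], num_classes=2)
        assert res.map50 == 1.0 and res.map5095 == 1.0

    def test_zero_detections_scores_zero(self):
        gt = BoxSet(np.array([[5, 5, 20, 20]]), np.array([0]))
        res = evaluate_map([BoxSet.empty()], [gt], num_classes=1)
        assert res.map50 == 0.0 and res.map5095 == 0.0

    def test_hand_built_pr_curve(self):
        """Two GT, three detections (TP 0.9, FP 0.8, TP 0.7):
        101-point AP = (51 * 1 + 50 * 2/3) / 101."""
        gt = BoxSet(np.array([[0, 0, 10, 10], [20, 20, 30, 30]]), np.array([0, 0]))
        det = BoxSet(np.array([[0, 0, 10, 10], [50, 50, 60, 60], [20, 20, 30, 30]]),
                     np.array([0, 0, 0]), np.array([0.9, 0.8, 0.7]))
        res = evaluate_map([det], [gt], num_classes=1)
        assert res.map50 == pytest.approx((51 * 1.0 + 50 * (2 / 3)) / 101, abs=1e-9)

    def test_oracle_equivalence_on_randomized_scenes(self):
        """Package evaluator vs the naive reference implementation, 50 scenes."""
        rng = np.random.default_rng(2024)
        thresholds = tuple(np.round(np.arange(0.5, 1.0, 0.05), 2))
        for _ in range(50):
            dets, gts = _random_scene_set(rng)
            res = evaluate_map(dets, gts, thresholds, num_classes=3)
            o50, o5095 = oracle_map(dets, gts, thresholds, num_classes=3)
            assert res.map50 == pytest.approx(o50, abs=1e-6)
            assert res.map5095 == pytest.approx(o5095, abs=1e-6)

    def test_map5095_never_exceeds_map50(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            dets, gts = _random_scene_set(rng)
            res = evaluate_map(dets, gts, num_classes=3)
            assert res.map5095 <= res.map50 + 1e-9


class TestAssignment:
    def test_every_gt_receives_a_location(self, rng):
        centers = np.stack(np.meshgrid(np.arange(8) * 8 + 4, np.arange(8) * 8 + 4),
                           axis=-1).reshape(-1, 2).astype(np.float32)
        strides = np.full(64, 8, dtype=np.float32)
        gt = np.array([[4, 4, 28, 28], [36, 36, 60, 60]], dtype=np.float32)
        pred = np.tile(np.array([0, 0, 10, 10], dtype=np.float32), (64, 1))
        fg, matched = simota_assign(pred, np.zeros(64), np.zeros((64, 3)),
                                    gt, np.array([0, 1]), centers, strides)
        assert set(matched.tolist()) == {0, 1}
        assert len(fg) == len(matched) and len(np.unique(fg)) == len(fg)


class TestTrainingLoop:
    @pytest.fixture()
    def small64(self):
        return generate_dataset(SceneConfig(image_size=64, seed=21,
                                            night_probability=0.0, rain_probability=0.0), 4)

    def _schedule(self, **kw):
        kw.setdefault("epochs", 2)
        kw.setdefault("aug_epochs", 0)
        kw.setdefault("batch_size", 2)
        kw.setdefault("lr_init", 1e-3)
        kw.setdefault("optimizer", "adam")
        return TrainSchedule(**kw)

    def test_epoch_bookkeeping_matches_cosine(self, tiny_config, small64):
        model = build_model(tiny_config, seed=0)
        sched = self._schedule()
        _, log = train(model, small64, sched, seed=0, input_size=64)
        iters = [r for r in log if "total" in r]
        assert {r["epoch"] for r in iters} == {0, 1}
        for r in iters:
            assert r["lr"] == pytest.approx(cosine_lr(r["epoch"], sched))

    def test_same_seed_same_first_iteration_loss(self, tiny_config, small64):
        losses = []
        for _ in range(2):
            model = build_model(tiny_config, seed=7)
            _, log = train(model, small64, self._schedule(epochs=1), seed=7,
                           input_size=64, max_iters=1)
            losses.append([r for r in log if "total" in r][0]["total"])
        assert losses[0] == losses[1]

    def test_empty_dataset_rejected(self, tiny_config):
        from wildtrap.synthetic_data import Dataset

        with pytest.raises(ValueError):
            train(build_model(tiny_config, seed=0), Dataset([]), self._schedule())

    def test_nan_loss_aborts_with_component_name(self, tiny_config, small64):
        model = build_model(tiny_config, seed=0)
        model.head.obj_preds[0].bias.data[...] = np.inf
        with pytest.raises(NaNLossError, match="obj"):
            train(model, small64, self._schedule(epochs=1), seed=0, input_size=64,
                  max_iters=1)

    def test_augmentation_off_is_deterministic_plain_resize(self, small64):
        rng1 = np.random.default_rng(0)
        rng2 = np.random.default_rng(99)       # rng must not matter when aug is off
        b1, g1 = make_batch(small64, [0, 1], 64, False, rng1)
        b2, g2 = make_batch(small64, [0, 1], 64, False, rng2)
        np.testing.assert_array_equal(b1, b2)
        src = small64.scenes[0].image.astype(np.float32) / 255.0
        np.testing.assert_allclose(b1[0].transpose(1, 2, 0), src, atol=1e-6)

    def test_augmented_batches_differ_from_plain(self, small64):
        rng = np.random.default_rng(1)
        plain, _ = make_batch(small64, [0, 1, 2, 3], 64, False, rng)
        augd, _ = make_batch(small64, [0, 1, 2, 3], 64, True, np.random.default_rng(1))
        assert not np.allclose(plain, augd)


class TestDiagnostics:
    def test_render_empty_boxset_returns_image_unchanged(self, rng):
        img = (rng.random((32, 32, 3)) * 255).astype(np.uint8)
        out = render_detections(img, BoxSet.empty())
        np.testing.assert_array_equal(out, img)

    def test_render_draws_boxes(self, rng):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        det = BoxSet(np.array([[8, 8, 40, 40]]), np.array([1]), np.array([0.9]))
        out = render_detections(img, det)
        assert (out != img).any()

    def test_heatmap_normalized_and_sized(self, tiny_model, rng):
        img = (rng.random((64, 64, 3)) * 255).astype(np.uint8)
        cam = activation_heatmap(tiny_model, img, input_size=64)
        assert cam.shape == (64, 64)
        assert cam.min() >= 0.0 and cam.max() <= 1.0
        tiny_model.zero_grad()

    def test_zero_weight_head_gives_flat_map(self, tiny_config, rng):
        model = build_model(tiny_config, seed=0)
        for mods in (model.head.cls_preds, model.head.obj_preds, model.head.reg_preds):
            for conv in mods:
                conv.weight.data[...] = 0.0
                conv.bias.data[...] = 0.0
        img = (rng.random((64, 64, 3)) * 255).astype(np.uint8)
        cam = activation_heatmap(model, img, input_size=64)
        assert cam.max() - cam.min() == pytest.approx(0.0, abs=1e-7)
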
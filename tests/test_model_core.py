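"""Detector assembly, architecture accounting, decoding, and I/O contracts."""

import numpy as np
import pytest

from wildtrap import nn
from wildtrap.model_core import (
    BoxSet,
    ConfigError,
    ModelConfig,
    build_model,
    count_flops,
    count_parameters,
    decode_predictions,
    detections_to_coco_json,
    load_checkpoint,
    nms_greedy,
    round_half_up,
    save_checkpoint,
)


class TestConfig:
    @pytest.mark.parametrize("bad", [
        {"depth_multiple": 0}, {"width_multiple": -1}, {"num_classes": 0},
        {"input_size": 300}, {"refine_mode": "inside_out"}, {"dyhead_stacks": -1},
        {"box_loss": "l1"}, {"focal_gamma": -0.5},
    ])
    def test_invalid_field_raises_named_error(self, bad):
        with pytest.raises(ConfigError) as err:
            ModelConfig(**bad).validate()
        assert next(iter(bad)) in str(err.value)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = ModelConfig(dyhead_stacks=3, box_loss="giou", input_size=320)
        path = tmp_path / "model.yaml"
        cfg.save_yaml(path)
        assert ModelConfig.load_yaml(path) == cfg

    def test_equal_configs_build_identical_counts(self, tiny_config):
        m1 = build_model(tiny_config, seed=0)
        m2 = build_model(tiny_config, seed=5)  # different init, same architecture
        assert count_parameters(m1) == count_parameters(m2)
        assert count_flops(m1, 64) == count_flops(m2, 64)


class TestAccounting:
    def test_single_conv_closed_form(self):
        conv = nn.Conv2d(3, 8, 1, bias=True)
        assert conv.num_parameters() == 3 * 8 + 8 == 32

    def test_optional_modules_add_parameters(self, tiny_config):
        base = build_model(tiny_config, seed=0)
        with_head = build_model(ModelConfig.baseline(
            width_multiple=0.125, input_size=64, dyhead_stacks=2), seed=0)
        assert count_parameters(with_head) > count_parameters(base)

    def test_params_invariant_to_input_size_but_flops_not(self, tiny_model):
        p = count_parameters(tiny_model)
        f64, f128 = count_flops(tiny_model, 64), count_flops(tiny_model, 128)
        assert count_parameters(tiny_model) == p
        assert f128 > f64

    def test_conv_flops_scale_with_input_area(self):
        """Doubling both spatial dims multiplies convolutional cost by 4."""
        conv = nn.Conv2d(4, 4, 3, bias=False)
        def macs(size):
            with nn.no_grad(), nn.count_macs() as ops:
                conv(nn.Tensor(np.zeros((1, 4, size, size), dtype=np.float32)))
            return ops["macs"]
        assert macs(20) == 4 * macs(10)

    def test_indivisible_input_size_rejected(self, tiny_model):
        with pytest.raises(ConfigError):
            count_flops(tiny_model, 100)

    def test_round_half_up(self):
        assert round_half_up(8.95) == 9.0
        assert round_half_up(8.94) == 8.9
        assert round_half_up(26.75) == 26.8


class TestDecode:
    def _raw_single_level(self, nc=2, h=4, w=4):
        """Raw outputs with one stride-8 level; others empty-ish maps."""
        reg = np.full((1, 4, h, w), -20.0, dtype=np.float32)
        obj = np.full((1, 1, h, w), -20.0, dtype=np.float32)
        cls = np.full((1, nc, h, w), -20.0, dtype=np.float32)
        return reg, obj, cls

    def _as_levels(self, reg, obj, cls):
        # strides 16/32 levels carry no activations
        lv2 = tuple(np.full((1, c, 2, 2), -20.0, dtype=np.float32) for c in (4, 1, cls.shape[1]))
        lv3 = tuple(np.full((1, c, 1, 1), -20.0, dtype=np.float32) for c in (4, 1, cls.shape[1]))
        return [(reg, obj, cls), lv2, lv3]

    def test_pinned_decode_formula(self):
        """Grid cell (2, 3) at stride 8, deltas (0.5, 0.5), sizes (ln2, ln2)
        decodes to center (20, 28) and a 16 x 16 box."""
        reg, obj, cls = self._raw_single_level()
        reg[0, 0, 3, 2] = 0.5
        reg[0, 1, 3, 2] = 0.5
        reg[0, 2, 3, 2] = np.log(2.0)
        reg[0, 3, 3, 2] = np.log(2.0)
        obj[0, 0, 3, 2] = 5.0
        cls[0, 0, 3, 2] = 5.0
        dets = decode_predictions(self._as_levels(reg, obj, cls), 0.5, 0.65)[0]
        assert len(dets) == 1
        np.testing.assert_allclose(dets.boxes[0], [20 - 8, 28 - 8, 20 + 8, 28 + 8], atol=1e-4)

    def test_identical_boxes_suppressed_to_one(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10]], dtype=np.float32)
        keep = nms_greedy(boxes, np.array([0.9, 0.9], dtype=np.float32), 0.5)
        assert len(keep) == 1

    def test_conf_threshold_one_empties_output(self):
        dets = decode_predictions(self._as_levels(*self._raw_single_level()), 1.0, 0.5)[0]
        assert len(dets) == 0

    def test_boxes_clipped_and_sorted(self, tiny_model, rng):
        x = rng.normal(size=(1, 3, 64, 64)).astype(np.float32)
        tiny_model.eval()
        with nn.no_grad():
            raw = tiny_model(x)
        dets = decode_predictions(raw, 0.01, 0.65, input_size=64)[0]
        if len(dets):
            assert dets.boxes.min() >= 0 and dets.boxes.max() <= 64
            assert (np.diff(dets.scores) <= 1e-7).all()

    def test_nms_output_subset_of_input(self, rng):
        boxes = rng.uniform(0, 50, size=(30, 2)).astype(np.float32)
        boxes = np.concatenate([boxes, boxes + rng.uniform(5, 20, size=(30, 2))], axis=1)
        scores = rng.uniform(0, 1, 30).astype(np.float32)
        keep = nms_greedy(boxes, scores, 0.5)
        assert set(keep.tolist()) <= set(range(30))


class TestBoxSet:
    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            BoxSet(np.array([[5, 5, 3, 8]]), np.array([0])).validate()
        with pytest.raises(ValueError):
            BoxSet(np.array([[0, 0, 1, 1]]), np.array([0]), np.array([1.5])).validate()


class TestCheckpoint:
    def test_roundtrip_and_backbone_only_load(self, tiny_config, tmp_path):
        m1 = build_model(tiny_config, seed=0)
        m2 = build_model(tiny_config, seed=9)
        path = tmp_path / "w.npz"
        save_checkpoint(m1, path)
        missing, unexpected = load_checkpoint(m2, path)
        assert not missing and not unexpected
        np.testing.assert_array_equal(m2.head.cls_preds[0].weight.data,
                                      m1.head.cls_preds[0].weight.data)
        # partial (backbone-only) mapping reports unmatched head/neck keys
        m3 = build_model(tiny_config, seed=9)
        state = {k: v for k, v in m1.state_dict().items() if k.startswith("extractor.")}
        np.savez(tmp_path / "bb.npz", **state)
        missing, unexpected = load_checkpoint(m3, tmp_path / "bb.npz")
        assert missing and not unexpected
        assert all(not k.startswith("extractor.") for k in missing)

    def test_detections_export_format(self, tmp_path):
        det = BoxSet(np.array([[10, 20, 30, 40]]), np.array([2]), np.array([0.7]))
        records = detections_to_coco_json({5: det}, tmp_path / "dets.json")
        assert records == [{"image_id": 5, "category_id": 3,
                            "bbox": [10.0, 20.0, 20.0, 20.0], "score": pytest.approx(0.7)}]
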
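"""Dynamic-head attention reductions, stacking, and accounting."""

import numpy as np
import pytest

from wildtrap import nn
from wildtrap.dyhead import (
    DyHead,
    ScaleAttention,
    SpatialAttention,
    TaskAttention,
    dyhead_forward,
    hard_sigmoid,
)
from wildtrap.model_core import ModelConfig, build_model, count_flops, count_parameters


def _t(a, grad=False):
    return nn.Tensor(np.asarray(a, dtype=np.float32), requires_grad=grad)


def _levels(rng, n=1, c=8, h=6, w=6, k=3):
    return [_t(rng.normal(size=(n, c, h, w))) for _ in range(k)]


class TestScaleAttention:
    def test_zero_init_gate_halves_features(self, rng):
        attn = ScaleAttention()
        levels = _levels(rng)
        out = attn(levels)
        for f, o in zip(levels, out):
            np.testing.assert_allclose(o.data, f.data * 0.5, atol=1e-6)

    def test_identical_levels_get_identical_gates(self, rng):
        attn = ScaleAttention()
        attn.fc.weight.data[...] = 0.7
        attn.fc.bias.data[...] = 0.1
        f = _t(rng.normal(size=(2, 4, 5, 5)))
        o1, o2, o3 = attn([f, f, f])
        np.testing.assert_allclose(o1.data, o2.data)
        np.testing.assert_allclose(o2.data, o3.data)

    def test_gate_saturates_at_one(self, rng):
        attn = ScaleAttention()
        attn.fc.weight.data[...] = 0.0
        attn.fc.bias.data[...] = 5.0          # statistic >= 1 after the linear map
        f = _t(rng.normal(size=(1, 3, 4, 4)))
        np.testing.assert_allclose(attn([f])[0].data, f.data, atol=1e-6)

    def test_gates_bounded(self, rng):
        x = _t(rng.normal(size=(7, 1)) * 10)
        g = hard_sigmoid(x).data
        assert g.min() >= 0.0 and g.max() <= 1.0


class TestSpatialAttention:
    def test_degenerate_case_equals_plain_convolution(self, rng):
        """Zero offsets and unit masks reduce the deformable aggregation to a
        standard 3x3 convolution with the same weights."""
        with nn.init_rng(np.random.default_rng(0)):
            attn = SpatialAttention(6)
        f = _t(rng.normal(size=(2, 6, 7, 7)))
        offsets = _t(np.zeros((2, 18, 7, 7)))
        mask = _t(np.ones((2, 9, 7, 7)))
        out = attn._aggregate(f, offsets, mask)
        ref = nn.conv2d(f, attn.weight, attn.bias, stride=1, padding=1)
        np.testing.assert_allclose(out.data, ref.data, atol=1e-5)

    def test_zero_masks_zero_output(self, rng):
        with nn.init_rng(np.random.default_rng(0)):
            attn = SpatialAttention(4)
        attn.bias.data[...] = 0.0
        f = _t(rng.normal(size=(1, 4, 5, 5)))
        out = attn._aggregate(f, _t(np.zeros((1, 18, 5, 5))), _t(np.zeros((1, 9, 5, 5))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-6)

    def test_constant_input_interior_value(self, rng):
        """On a constant map with zero offsets and unit masks, interior outputs
        equal (sum of weights) * input value."""
        with nn.init_rng(np.random.default_rng(0)):
            attn = SpatialAttention(3)
        attn.bias.data[...] = 0.0
        f = _t(np.full((1, 3, 9, 9), 2.0))
        out = attn._aggregate(f, _t(np.zeros((1, 18, 9, 9))), _t(np.ones((1, 9, 9, 9))))
        wsum = attn.weight.data.sum(axis=(1, 2, 3))          # per out-channel
        np.testing.assert_allclose(out.data[0, :, 4, 4], 2.0 * wsum, rtol=1e-4)

    def test_masks_bounded_by_sigmoid(self, rng):
        with nn.init_rng(np.random.default_rng(0)):
            attn = SpatialAttention(4)
        attn.offset_conv.weight.data[...] = rng.normal(size=attn.offset_conv.weight.shape)
        levels = _levels(rng, c=4, h=5, w=5)
        branch = attn.offset_conv(levels[1])
        m = branch[:, 18:].sigmoid().data
        assert m.min() >= 0.0 and m.max() <= 1.0


class TestTaskAttention:
    def test_identity_at_initialization(self, rng):
        """(alpha1, alpha2, beta1, beta2) = (1, 0, 0, 0) gives max(F, 0); on
        non-negative input the block is the identity."""
        with nn.init_rng(np.random.default_rng(0)):
            attn = TaskAttention(6)
        f = _t(np.abs(rng.normal(size=(2, 6, 4, 4))))
        out = attn([f, f, f])
        for o in out:
            np.testing.assert_allclose(o.data, f.data, atol=1e-6)
        g = _t(rng.normal(size=(1, 6, 4, 4)))
        np.testing.assert_allclose(attn([g])[0].data, np.maximum(g.data, 0.0), atol=1e-6)

    def test_equal_branches_degenerate_max(self, rng):
        with nn.init_rng(np.random.default_rng(0)):
            attn = TaskAttention(4)
        attn._coeff_init = np.concatenate([
            np.full(4, 0.7), np.full(4, 0.7), np.full(4, 0.2), np.full(4, 0.2),
        ]).astype(np.float32)
        f = _t(rng.normal(size=(1, 4, 3, 3)))
        np.testing.assert_allclose(attn([f])[0].data, 0.7 * f.data + 0.2, atol=1e-5)

    def test_absolute_value_coefficients(self):
        """(1, -1, 0, 0) turns the piecewise max into |F|."""
        with nn.init_rng(np.random.default_rng(0)):
            attn = TaskAttention(1)
        attn._coeff_init = np.array([1.0, -1.0, 0.0, 0.0], dtype=np.float32)
        f = _t(np.array([-2.0, -1.0, 0.0, 1.0]).reshape(1, 1, 2, 2))
        np.testing.assert_allclose(attn([f])[0].data.reshape(-1), [2, 1, 0, 1], atol=1e-6)

    def test_coefficients_always_bounded(self, rng):
        with nn.init_rng(np.random.default_rng(0)):
            attn = TaskAttention(4)
        attn.fc2.weight.data[...] = rng.normal(size=attn.fc2.weight.shape) * 10
        attn.fc2.bias.data[...] = rng.normal(size=attn.fc2.bias.shape) * 10
        coef = attn.coefficients(_levels(rng, c=4)).data
        assert coef.min() >= -1.0 and coef.max() <= 1.0


class TestDyHeadForward:
    def test_zero_stacks_is_identity(self, rng):
        feats = [_t(rng.normal(size=(1, 4, s, s))) for s in (8, 4, 2)]
        out = dyhead_forward(feats, 0)
        assert out is feats

    def test_shape_preserving_composition(self, rng):
        cfg = ModelConfig(width_multiple=0.125, dyhead_stacks=2)
        with nn.init_rng(np.random.default_rng(0)):
            head = DyHead(cfg)
        feats = [_t(rng.normal(size=(2, c, s, s)))
                 for c, s in zip((32, 64, 128), (8, 4, 2))]
        out = head(feats)
        for f, o in zip(feats, out):
            assert o.shape == f.shape

    def test_parameters_linear_in_stack_count(self):
        counts = {}
        for k in (1, 2, 4):
            cfg = ModelConfig(width_multiple=0.125, dyhead_stacks=k)
            with nn.init_rng(np.random.default_rng(0)):
                counts[k] = DyHead(cfg).num_parameters()
        per_stack = counts[2] - counts[1]
        assert counts[4] - counts[2] == 2 * per_stack
        assert per_stack > 0

    def test_model_flops_affine_in_stacks(self):
        """FLOPs added per DyHead stack are constant (affine in stack count)."""
        flops = {}
        for k in (0, 1, 2, 4):
            cfg = ModelConfig.baseline(width_multiple=0.125, input_size=128,
                                       dyhead_stacks=k)
            flops[k] = count_flops(build_model(cfg), 128)
        per_stack = flops[2] - flops[1]
        assert flops[1] - flops[0] > per_stack > 0   # first stack adds unification cost too
        assert flops[4] - flops[2] == 2 * per_stack

    def test_model_params_strictly_increasing_in_stacks(self):
        prev = None
        for k in (0, 1, 2, 4):
            cfg = ModelConfig.baseline(width_multiple=0.125, dyhead_stacks=k)
            p = count_parameters(build_model(cfg))
            if prev is not None:
                assert p > prev
            prev = p
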
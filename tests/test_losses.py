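"""Perceptual/L1/SSIM objectives against brute-force nested-loop oracles."""

import numpy as np
import pytest

from uperc3d import (LossNetConfig, build_loss_network, extract_features,
                     l1_loss, perceptual_loss, ssim_objective, ssim3d)
from uperc3d.loss_networks import FeatureExtractor
from uperc3d.nn import Conv3d, Identity, ReLU, Tensor
from oracles import mean_abs_loops, perceptual_loss_loops


def _identity_extractor() -> FeatureExtractor:
    """Single 1x1x1 conv fixed to weight 1, bias 0, linear activation."""
    conv = Conv3d(1, 1, 1, rng=np.random.default_rng(0))
    conv.weight.data = np.ones((1, 1, 1, 1, 1), dtype=np.float32)
    conv.bias.data = np.zeros(1, dtype=np.float32)
    return FeatureExtractor([conv, Identity()], [1])


class TestExtractFeatures:
    def test_depth3_feature_dims(self, small_phantom):
        ex = build_loss_network(LossNetConfig(depth=3, n_features=32))
        fm = extract_features(ex, small_phantom)
        assert len(fm) == 3
        assert fm.dims == [(32, 32, 32, 32)] * 3
        assert fm.maps[0].shape == (32, 32, 32, 32)

    def test_pooled_feature_dims_counted_by_hand(self, rng):
        ex = build_loss_network(LossNetConfig(depth=3, pooling_after=(1, 2)))
        fm = extract_features(ex, rng.random((16, 16, 16), dtype=np.float32))
        # shape law: tap j = input / 2^(pools strictly before layer j)
        assert [d[1:] for d in fm.dims] == [(16,) * 3, (8,) * 3, (4,) * 3]

    def test_zero_input_zero_bias_gives_zero_maps(self):
        ex = build_loss_network(LossNetConfig(depth=2, init_method="xavier_normal"))
        fm = extract_features(ex, np.zeros((8, 8, 8), dtype=np.float32))
        for m in fm.maps:
            assert np.all(m == 0)

    def test_incompatible_pooled_dims_raise(self):
        ex = build_loss_network(LossNetConfig(depth=2, pooling_after=(1, 2)))
        with pytest.raises(ValueError, match="spatial|pooling"):
            extract_features(ex, np.zeros((2, 2, 2), dtype=np.float32))


class TestPerceptualLoss:
    def test_equal_inputs_give_zero_everywhere(self, small_phantom):
        ex = build_loss_network(LossNetConfig())
        lv = perceptual_loss(ex, small_phantom, small_phantom)
        assert lv.value == 0.0
        assert all(c == 0.0 for c in lv.per_layer)

    def test_identity_extractor_collapses_to_mse(self, rng):
        ex = _identity_extractor()
        for _ in range(5):
            a = rng.random((5, 5, 5), dtype=np.float32)
            b = rng.random((5, 5, 5), dtype=np.float32)
            lv = perceptual_loss(ex, a, b)
            assert lv.value == pytest.approx(float(np.mean((a - b) ** 2)), rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nested_loop_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        cfg = LossNetConfig(depth=2, n_features=2, kernel_size=3, seed=seed)
        ex = build_loss_network(cfg)
        weights = [(l.weight.data, l.bias.data)
                   for l in ex.layers if isinstance(l, Conv3d)]
        a = rng.random((4, 4, 4), dtype=np.float32)
        b = rng.random((4, 4, 4), dtype=np.float32)
        expected = perceptual_loss_loops(weights, a, b)
        got = perceptual_loss(ex, a, b)
        assert got.value == pytest.approx(expected, rel=1e-5)
        assert got.value == pytest.approx(sum(got.per_layer), rel=1e-6)

    def test_symmetric_in_its_arguments(self, rng):
        ex = build_loss_network(LossNetConfig(depth=2, n_features=4))
        a = rng.random((6, 6, 6), dtype=np.float32)
        b = rng.random((6, 6, 6), dtype=np.float32)
        assert perceptual_loss(ex, a, b).value == pytest.approx(
            perceptual_loss(ex, b, a).value, rel=1e-6)

    def test_gradient_reaches_pred_but_not_extractor(self, rng):
        ex = build_loss_network(LossNetConfig(depth=2, n_features=4))
        pred = Tensor(rng.random((1, 1, 8, 8, 8), dtype=np.float32), requires_grad=True)
        target = rng.random((1, 1, 8, 8, 8), dtype=np.float32)
        lv = perceptual_loss(ex, pred, target)
        lv.tensor.backward()
        assert pred.grad is not None and np.abs(pred.grad).max() > 0
        assert all(p.grad is None for p in ex.parameters())

    def test_shape_mismatch_raises(self, rng):
        ex = build_loss_network(LossNetConfig())
        with pytest.raises(ValueError, match="mismatch"):
            perceptual_loss(ex, rng.random((4, 4, 4)), rng.random((4, 4, 5)))


class TestL1Loss:
    def test_zero_for_equal_and_offset_value(self, rng):
        a = rng.random((5, 5, 5), dtype=np.float32)
        assert l1_loss(a, a) == 0.0
        assert l1_loss(a + 0.5, a) == pytest.approx(0.5, rel=1e-6)

    def test_matches_nested_loop_oracle(self, rng):
        a = rng.random((4, 4, 4), dtype=np.float32)
        b = rng.random((4, 4, 4), dtype=np.float32)
        assert l1_loss(a, b) == pytest.approx(mean_abs_loops(a, b), rel=1e-6)


class TestSSIMObjective:
    def test_zero_for_identical_volumes(self, small_phantom):
        assert ssim_objective(small_phantom.data, small_phantom.data) == pytest.approx(0.0, abs=1e-7)

    def test_inverted_binary_volume_near_range_maximum(self):
        rng = np.random.default_rng(0)
        target = (rng.random((16, 16, 16)) > 0.5).astype(np.float32)
        pred = 1.0 - target
        val = ssim_objective(pred, target)
        assert val > 1.0  # SSIM < 0: structure fully anti-correlated

    def test_consistent_with_metrics_ssim3d(self, rng):
        a = rng.random((14, 14, 14), dtype=np.float32)
        b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1).astype(np.float32)
        assert ssim_objective(a, b) == pytest.approx(1.0 - ssim3d(a, b), abs=1e-6)

    def test_gradient_flows_to_prediction(self, rng):
        pred = Tensor(rng.random((1, 1, 12, 12, 12), dtype=np.float32),
                      requires_grad=True)
        target = rng.random((1, 1, 12, 12, 12), dtype=np.float32)
        out = ssim_objective(pred, target)
        out.backward()
        assert np.abs(pred.grad).max() > 0
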
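"""Frozen random feature extractors: shapes, pooling, initialization schemes."""

import numpy as np
import pytest

from uperc3d import (LossNetConfig, build_loss_network, build_preset_alexnet_3d,
                     build_preset_vgg19_3d, initialize_weights)
from uperc3d.nn import Conv3d, Tensor


def _taps(extractor, edge=16, seed=0):
    x = Tensor(np.random.default_rng(seed).random((1, 1, edge, edge, edge),
                                                  dtype=np.float32))
    return extractor(x)


class TestSimplePreset:
    def test_default_three_layer_net_shapes(self):
        ex = build_loss_network(LossNetConfig(depth=3, kernel_size=3, n_features=32))
        taps = _taps(ex, edge=16)
        assert len(taps) == 3
        for t in taps:
            assert t.shape == (1, 32, 16, 16, 16)

    @pytest.mark.parametrize("pooling,expected", [
        ((1,), [32, 16, 16]),
        ((1, 2), [32, 16, 8]),
        ((1, 2, 3), [32, 16, 8]),  # third pool sits after the last tap
    ])
    def test_pooling_halves_later_taps(self, pooling, expected):
        # tap j is taken before any pool that follows layer j
        ex = build_loss_network(LossNetConfig(depth=3, pooling_after=pooling))
        taps = _taps(ex, edge=32)
        assert [t.shape[2] for t in taps] == expected

    def test_pooling_shape_law(self):
        # tap j spatial size = input / 2^(pools at or before j)
        ex = build_loss_network(LossNetConfig(depth=5, pooling_after=(1, 2, 3)))
        taps = _taps(ex, edge=32)
        assert [t.shape[2] for t in taps] == [32, 16, 8, 4, 4]

    @pytest.mark.parametrize("depth", [3, 5, 7, 9, 13])
    def test_all_protocol_depths_run_on_small_input(self, depth):
        ex = build_loss_network(LossNetConfig(depth=depth))
        taps = _taps(ex, edge=16)
        assert len(taps) == depth

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            LossNetConfig(kernel_size=4)
        with pytest.raises(ValueError, match="out of range"):
            LossNetConfig(depth=3, pooling_after=(4,))
        with pytest.raises(ValueError, match="init"):
            LossNetConfig(init_method="magic")


class TestInitialization:
    def test_default_uniform_bound_is_reciprocal_fan_in(self):
        # printed bound: k = 1/(C_in * prod K_i) = 1/(32*27) = 1/864
        ex = build_loss_network(LossNetConfig(depth=2, n_features=32,
                                              init_method="default_uniform"))
        conv = ex.layers[2]  # second conv: 32 -> 32, 3^3 kernel
        assert isinstance(conv, Conv3d) and conv.in_channels == 32
        k = 1.0 / 864.0
        w = conv.weight.data
        assert np.abs(w).max() <= k
        assert w.max() - w.min() >= 0.9 * 2 * k  # fills the band
        assert np.abs(conv.bias.data).max() <= k

    def test_legacy_sqrt_bound_variant(self):
        ex = build_loss_network(LossNetConfig(depth=2, init_method="default_uniform",
                                              legacy_sqrt_bound=True))
        w = ex.layers[2].weight.data
        assert np.abs(w).max() <= 1.0 / np.sqrt(864.0)
        assert np.abs(w).max() > 1.0 / 864.0

    def test_xavier_normal_variance_matches_closed_form(self):
        ex = build_loss_network(LossNetConfig(depth=3, n_features=32,
                                              init_method="xavier_normal", seed=11))
        w = ex.layers[2].weight.data  # 32*27*32 ~ 2.8e4 weights
        expected = 2.0 / (864 + 864)
        assert w.var() == pytest.approx(expected, rel=0.10)

    def test_kaiming_normal_variance_matches_closed_form(self):
        ex = build_loss_network(LossNetConfig(depth=3, init_method="kaiming_normal",
                                              seed=2))
        w = ex.layers[2].weight.data
        assert w.var() == pytest.approx(2.0 / 864, rel=0.10)

    def test_same_seed_reproduces_weights_different_seed_does_not(self):
        a = build_loss_network(LossNetConfig(seed=4))
        b = build_loss_network(LossNetConfig(seed=4))
        c = build_loss_network(LossNetConfig(seed=5))
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)
        assert any(not np.array_equal(pa.data, pc.data)
                   for pa, pc in zip(a.parameters(), c.parameters()))

    def test_reinitialization_names_valid_methods_on_error(self):
        ex = build_loss_network(LossNetConfig())
        with pytest.raises(ValueError, match="kaiming_uniform.*default_uniform"):
            initialize_weights(ex, "glorot", seed=0)


class TestPresets:
    def test_vgg19_channel_progression_and_tap_count(self):
        ex = build_preset_vgg19_3d(seed=0)
        convs = [l for l in ex.layers if isinstance(l, Conv3d)]
        assert convs[0].out_channels == 64
        assert [c.out_channels for c in convs] == [64, 64, 128, 128, 256, 256, 256, 256]
        taps = _taps(ex, edge=32)
        assert len(taps) >= 8
        assert taps[0].shape[1] == 64

    def test_alexnet_channels_and_input_contract(self):
        ex = build_preset_alexnet_3d(seed=0)
        convs = [l for l in ex.layers if isinstance(l, Conv3d)]
        assert [c.out_channels for c in convs] == [64, 192, 384, 256, 256]
        taps = _taps(ex, edge=48)
        assert taps[0].shape[1] == 64
        with pytest.raises(ValueError, match="spatial"):
            _taps(ex, edge=4)

    def test_presets_are_frozen_and_deterministic(self):
        a = build_preset_alexnet_3d(seed=1)
        b = build_preset_alexnet_3d(seed=1)
        assert a.checksum() == b.checksum()
        assert all(not p.requires_grad for p in a.parameters())
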
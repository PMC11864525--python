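"""SSIM/PSNR/MSE, evaluation-region cropping, aggregation."""

import math

import numpy as np
import pytest

from uperc3d import (CropSpec, EvalResult, Volume3D, aggregate, crop_eval_region,
                     mse, psnr, ssim3d)
from oracles import mse_loops, ssim3d_loops


class TestSSIM:
    def test_self_similarity_is_exactly_one(self, rng):
        x = rng.random((16, 16, 16))
        assert ssim3d(x, x, 1.0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_nested_loop_sliding_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((12, 12, 12))
        b = np.clip(a + rng.normal(0, 0.15, a.shape), 0, 1)
        assert ssim3d(a, b, 1.0) == pytest.approx(ssim3d_loops(a, b, 1.0), abs=1e-5)

    def test_constant_offset_strictly_penalized(self, rng):
        x = rng.random((12, 12, 12)) * 0.5
        assert ssim3d(x, x + 0.5, 1.0) < 1.0

    def test_symmetric(self, rng):
        a, b = rng.random((12, 12, 12)), rng.random((12, 12, 12))
        assert ssim3d(a, b) == pytest.approx(ssim3d(b, a), abs=1e-12)

    def test_small_volume_uses_largest_odd_window(self):
        x = np.random.default_rng(0).random((5, 5, 5))
        assert ssim3d(x, x) == pytest.approx(1.0)

    def test_window_larger_than_volume_rejected(self, rng):
        x = rng.random((6, 6, 6))
        with pytest.raises(ValueError, match="window"):
            ssim3d(x, x, win=11)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            ssim3d(rng.random((8, 8, 8)), rng.random((8, 8, 9)))


class TestPSNRandMSE:
    def test_psnr_closed_forms(self):
        a = np.zeros((10, 10, 10))
        b = np.full_like(a, 0.1)  # MSE 0.01
        assert psnr(a, b, 1.0) == pytest.approx(20.0, abs=1e-9)
        assert psnr(a, b, 2.0) - psnr(a, b, 1.0) == pytest.approx(10 * math.log10(4), abs=1e-9)

    def test_identical_volumes_give_infinity(self, rng):
        x = rng.random((6, 6, 6))
        assert psnr(x, x) == math.inf

    def test_psnr_monotone_in_noise_amplitude(self, rng):
        x = rng.random((10, 10, 10))
        noise = rng.normal(0, 1, x.shape)
        vals = [psnr(x, x + a * noise) for a in (0.01, 0.05, 0.1, 0.2)]
        assert all(u > v for u, v in zip(vals, vals[1:]))

    def test_mse_constant_difference_and_oracle(self, rng):
        x = rng.random((4, 4, 4))
        assert mse(x, x + 0.25) == pytest.approx(0.0625, rel=1e-9)
        y = rng.random((4, 4, 4))
        assert mse(x, y) == pytest.approx(mse_loops(x, y), rel=1e-12)


class TestCropping:
    def test_root_crop_geometry(self):
        vol = Volume3D(np.arange(160 * 160 * 160, dtype=np.float32).reshape(160, 160, 160))
        out = crop_eval_region(vol, CropSpec(kind="root"))
        assert out.shape == (52, 52, 52)
        assert out.data[0, 0, 0] == vol.data[0, 70, 70]

    def test_mra_crop_centered(self):
        vol = Volume3D(np.zeros((100, 512, 512), dtype=np.float32))
        vol.data[50, 256, 256] = 1.0
        out = crop_eval_region(vol, CropSpec(kind="mra"))
        assert out.shape == (68, 68, 68)
        assert out.data[34, 34, 34] == 1.0

    def test_none_returns_input_unchanged(self, small_phantom):
        assert crop_eval_region(small_phantom, CropSpec(kind="none")) is small_phantom

    def test_out_of_bounds_names_axis(self):
        vol = Volume3D(np.zeros((40, 200, 200), dtype=np.float32))
        with pytest.raises(ValueError, match="axis z"):
            crop_eval_region(vol, CropSpec(kind="root"))
        small = Volume3D(np.zeros((40, 40, 40), dtype=np.float32))
        with pytest.raises(ValueError, match="axis"):
            crop_eval_region(small, CropSpec(kind="mra"))

    def test_metric_commutes_with_identity_crop(self, small_phantom):
        spec = CropSpec(kind="none")
        assert ssim3d(crop_eval_region(small_phantom, spec), small_phantom) == 1.0


class TestAggregate:
    def test_single_value_mean_is_value_std_zero(self):
        r = EvalResult(region="none", seed=0)
        r.add(0.9, 30.0, 0.01)
        agg = aggregate([r])
        assert agg.aggregate["ssim"] == {"mean": 0.9, "std": 0.0,
                                         "seed_mean": 0.9, "seed_std": 0.0}

    def test_two_seed_means_average(self):
        r1 = EvalResult(region="none", seed=0)
        r2 = EvalResult(region="none", seed=1)
        for v in (0.8, 0.9):
            r1.add(v, 1.0, 0.0)
        for v in (0.6, 0.7):
            r2.add(v, 1.0, 0.0)
        agg = aggregate([r1, r2])
        assert agg.aggregate["ssim"]["seed_mean"] == pytest.approx((0.85 + 0.65) / 2)

    def test_matches_hand_computed_grid(self):
        # 3 images x 2 seeds of fabricated SSIMs
        grid = [[0.80, 0.85, 0.90], [0.70, 0.75, 0.95]]
        results = []
        for seed, row in enumerate(grid):
            r = EvalResult(region="none", seed=seed)
            for v in row:
                r.add(v, 10.0, 0.1)
            results.append(r)
        agg = aggregate(results).aggregate["ssim"]
        flat = [v for row in grid for v in row]
        assert agg["mean"] == pytest.approx(np.mean(flat))
        assert agg["std"] == pytest.approx(np.std(flat))
        assert agg["seed_mean"] == pytest.approx(np.mean([np.mean(r) for r in grid]))

    def test_empty_list_and_mixed_regions_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate([])
        r1, r2 = EvalResult(region="root"), EvalResult(region="mra")
        r1.add(1, 1, 1)
        r2.add(1, 1, 1)
        with pytest.raises(ValueError, match="region"):
            aggregate([r1, r2])

    def test_infinite_psnr_excluded_with_warning(self):
        r = EvalResult(region="none")
        r.add(1.0, math.inf, 0.0)
        r.add(0.9, 30.0, 0.01)
        with pytest.warns(UserWarning, match="infinite"):
            agg = aggregate([r])
        assert agg.aggregate["psnr"]["mean"] == pytest.approx(30.0)
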
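"""Evaluation protocol: 3D SSIM, PSNR, MSE, ROI cropping, aggregation.

SSIM follows the standard Gaussian-window formulation (sigma 1.5, window 11^3
where it fits, otherwise the largest odd window that does; constants
C1=(0.01 r)^2, C2=(0.03 r)^2 for data range r).  The local statistics are
evaluated only where the full window fits (valid region), and the mean local
SSIM is reported.  Evaluation regions mirror the study protocol: a 52^3 cube
anchored at z 0 / in-plane offset 70 for root-type volumes, and a centered
68^3 cube for angiography-type volumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume3D

__all__ = ["ssim3d", "psnr", "mse", "CropSpec", "crop_eval_region",
           "EvalResult", "aggregate", "evaluate_pair",
           "gaussian_kernel1d", "ssim_window_size"]

_AXES = ("z", "y", "x")


def _as_array(v) -> np.ndarray:
    return (v.data if isinstance(v, Volume3D) else np.asarray(v)).astype(np.float64)


def _check_pair(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def ssim_window_size(shape, requested: int | None = None) -> int:
    """11, or the largest odd window that fits the smallest axis."""
    m = min(shape)
    if requested is not None:
        if requested > m:
            raise ValueError(f"SSIM window {requested} larger than smallest axis ({m})")
        if requested % 2 == 0 or requested < 1:
            raise ValueError("SSIM window must be a positive odd integer")
        return requested
    w = min(11, m)
    return w if w % 2 == 1 else w - 1


def gaussian_kernel1d(size: int, sigma: float = 1.5) -> np.ndarray:
    """Normalized 1D Gaussian window of odd length ``size``."""
    r = size // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def ssim3d(a, b, data_range: float = 1.0, sigma: float = 1.5,
           win: int | None = None) -> float:
    """Mean local SSIM between two volumes over a sliding Gaussian window."""
    a, b = _as_array(a), _as_array(b)
    _check_pair(a, b)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    w = ssim_window_size(a.shape, win)
    k = gaussian_kernel1d(w, sigma)

    def blur(x: np.ndarray) -> np.ndarray:
        for ax in range(3):
            x = ndimage.correlate1d(x, k, axis=ax, mode="constant")
        r = w // 2
        return x[r:x.shape[0] - r or None, r:x.shape[1] - r or None, r:x.shape[2] - r or None]

    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_a, mu_b = blur(a), blur(b)
    var_a = blur(a * a) - mu_a ** 2
    var_b = blur(b * b) - mu_b ** 2
    cov = blur(a * b) - mu_a * mu_b
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)
    return float(np.mean(num / den))


def mse(a, b) -> float:
    """Mean squared voxel difference."""
    a, b = _as_array(a), _as_array(b)
    _check_pair(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(a, b, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio 10*log10(peak^2 / MSE), in dB (inf if MSE=0)."""
    if peak <= 0:
        raise ValueError("peak must be positive")
    err = mse(a, b)
    if err == 0:
        return math.inf
    return 10.0 * math.log10(peak * peak / err)


@dataclass
class CropSpec:
    """Evaluation region: 'root' (52^3 at z 0, in-plane 70), 'mra' (centered
    68^3), or 'none' (whole volume)."""

    kind: str = "none"
    root_edge: int = 52
    root_offset: int = 70
    mra_edge: int = 68

    def __post_init__(self):
        if self.kind not in ("root", "mra", "none"):
            raise ValueError(f"unknown crop kind {self.kind!r} (root, mra, none)")


def crop_eval_region(vol: Volume3D, spec: CropSpec) -> Volume3D:
    """Crop the protocol evaluation cube; out-of-bounds windows raise, never truncate."""
    if spec.kind == "none":
        return vol
    if spec.kind == "root":
        e, o = spec.root_edge, spec.root_offset
        starts, ends = (0, o, o), (e, o + e, o + e)
    else:
        e = spec.mra_edge
        centers = [s // 2 for s in vol.shape]
        starts = tuple(c - e // 2 for c in centers)
        ends = tuple(s + e for s in starts)
    for ax in range(3):
        if starts[ax] < 0 or ends[ax] > vol.shape[ax]:
            raise ValueError(
                f"crop window [{starts[ax]}, {ends[ax]}) exceeds axis "
                f"{_AXES[ax]} of size {vol.shape[ax]}")
    sl = tuple(slice(s, t) for s, t in zip(starts, ends))
    return Volume3D(vol.data[sl], vol.spacing, dict(vol.meta))


@dataclass
class EvalResult:
    """Per-image SSIM/PSNR/MSE triples plus (after aggregation) summary stats.

    ``aggregate`` maps metric name to mean/std over pooled images and, when
    several seed-level results are combined, over seed means.
    """

    per_image: list[tuple[float, float, float]] = field(default_factory=list)
    region: str = "none"
    seed: int | None = None
    aggregate: dict = field(default_factory=dict)

    def add(self, ssim_v: float, psnr_v: float, mse_v: float) -> None:
        self.per_image.append((float(ssim_v), float(psnr_v), float(mse_v)))

    def metric_values(self, idx: int) -> list[float]:
        return [t[idx] for t in self.per_image]


def evaluate_pair(pred: Volume3D, truth: Volume3D, crop: CropSpec | None = None,
                  data_range: float = 1.0) -> tuple[float, float, float]:
    """(SSIM, PSNR, MSE) of a prediction against ground truth, optionally cropped."""
    if crop is not None:
        pred = crop_eval_region(pred, crop)
        truth = crop_eval_region(truth, crop)
    return (ssim3d(pred, truth, data_range), psnr(pred, truth, data_range),
            mse(pred, truth))


def _mean_std(values: list[float], what: str) -> tuple[float, float]:
    vals = [v for v in values if math.isfinite(v)]
    if len(vals) < len(values):
        warnings.warn(f"excluding {len(values) - len(vals)} infinite {what} "
                      "value(s) from the mean", stacklevel=3)
    if not vals:
        return math.inf, 0.0
    return float(np.mean(vals)), float(np.std(vals))


def aggregate(results: list[EvalResult]) -> EvalResult:
    """Pool per-image metrics over seeds; report pooled and seed-level mean/std."""
    if not results:
        raise ValueError("cannot aggregate an empty result list")
    regions = {r.region for r in results}
    if len(regions) > 1:
        raise ValueError(f"inconsistent evaluation regions: {sorted(regions)}")
    out = EvalResult(region=results[0].region)
    for r in results:
        out.per_image.extend(r.per_image)
    for idx, name in enumerate(("ssim", "psnr", "mse")):
        pooled_mean, pooled_std = _mean_std(out.metric_values(idx), name)
        seed_means = [_mean_std(r.metric_values(idx), name)[0] for r in results]
        seed_mean, seed_std = _mean_std(seed_means, name)
        out.aggregate[name] = {
            "mean": pooled_mean, "std": pooled_std,
            "seed_mean": seed_mean, "seed_std": seed_std,
        }
    return out
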
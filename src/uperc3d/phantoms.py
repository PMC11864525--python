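"""Synthetic phantoms of line-like structures and Rician corruption.

Real training data for this problem are MR volumes of plant roots in soil and
brain-vessel angiograms: sparse, connected, curvilinear structures on a dark
background.  :func:`generate_phantom` emulates those properties with branching
tubes: each tube is a persistent random-walk centerline with bounded per-step
curvature, dilated to a radius with anti-aliased (soft) edges.

:func:`add_rician_noise` implements the standard magnitude-image corruption

    out = sqrt((vol + g1)^2 + g2^2),   g1, g2 ~ N(0, sigma^2) i.i.d.

with sigma defined as a fraction (the "noise level") of the clean volume's
peak intensity.  The four protocol levels are 1%, 5%, 10% and 20%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume3D

__all__ = ["PhantomConfig", "NoiseSpec", "generate_phantom", "add_rician_noise",
           "NOISE_LEVELS"]

#: The four protocol noise levels (fractions of peak intensity).
NOISE_LEVELS = (0.01, 0.05, 0.10, 0.20)


@dataclass
class PhantomConfig:
    """Geometry of a branching-tube phantom.

    shape : (z, y, x) volume dimensions, each >= 16.
    n_tubes : number of primary tubes.
    radius_range : (min, max) tube radius in voxels, min >= 0.5.
    branch_prob : probability per tube of spawning one child branch.
    tube_intensity_range : (min, max) tube intensity, within (0, 1].
    background_level : constant background in [0, 0.1].
    curvature : maximum per-step angular deviation of the centerline (radians).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    n_tubes: int = 5
    radius_range: tuple[float, float] = (1.0, 2.5)
    branch_prob: float = 0.3
    tube_intensity_range: tuple[float, float] = (0.6, 1.0)
    background_level: float = 0.02
    curvature: float = 0.3

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3:
            raise ValueError("shape must be (z, y, x)")
        if self.n_tubes < 0:
            raise ValueError("n_tubes must be >= 0")
        for name in ("radius_range", "tube_intensity_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (min <= max)")
        if self.radius_range[0] < 0.5:
            raise ValueError("minimum tube radius is 0.5 voxels")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must lie in [0, 1]")
        if not 0.0 < self.tube_intensity_range[0]:
            raise ValueError("tube intensities must be positive")
        if self.tube_intensity_range[1] > 1.0:
            raise ValueError("tube intensities must be <= 1")
        if not 0.0 <= self.background_level <= 0.1:
            raise ValueError("background_level must lie in [0, 0.1]")


@dataclass
class NoiseSpec:
    """Rician corruption: ``level`` is sigma as a fraction of peak intensity."""

    level: float
    seed: int = 0

    def __post_init__(self):
        if self.level < 0 or self.level >= 1:
            raise ValueError(f"noise level must lie in [0, 1), got {self.level}")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perturb_direction(d: np.ndarray, max_angle: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate ``d`` by a uniform random angle in [0, max_angle] about a random axis."""
    if max_angle <= 0:
        return d
    angle = rng.uniform(0.0, max_angle)
    # random axis orthogonal to d
    r = _random_unit(rng)
    axis = np.cross(d, r)
    n = np.linalg.norm(axis)
    if n < 1e-8:
        return d
    axis /= n
    out = d * np.cos(angle) + np.cross(axis, d) * np.sin(angle)
    return out / np.linalg.norm(out)


def _walk_centerline(start: np.ndarray, direction: np.ndarray, n_steps: int,
                     shape: tuple[int, int, int], curvature: float,
                     rng: np.random.Generator, step: float = 0.5) -> np.ndarray:
    """Persistent random walk with bounded curvature, reflecting at the walls."""
    pos = start.astype(float).copy()
    d = direction / np.linalg.norm(direction)
    pts = [pos.copy()]
    hi = np.asarray(shape, dtype=float) - 1.0
    for _ in range(n_steps):
        d = _perturb_direction(d, curvature, rng)
        pos = pos + step * d
        for ax in range(3):
            if pos[ax] < 0:
                pos[ax] = -pos[ax]
                d[ax] = -d[ax]
            elif pos[ax] > hi[ax]:
                pos[ax] = 2 * hi[ax] - pos[ax]
                d[ax] = -d[ax]
        pts.append(pos.copy())
    return np.asarray(pts)


def _tube_profile(shape: tuple[int, int, int], pts: np.ndarray, radius: float,
                  intensity: float) -> np.ndarray:
    """Centerline dilated to ``radius`` with a soft (anti-aliased) edge."""
    mask = np.zeros(shape, dtype=bool)
    idx = np.round(pts).astype(int)
    idx = np.clip(idx, 0, np.asarray(shape) - 1)
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    dist = ndimage.distance_transform_edt(~mask)
    # intensity ramps from full (inside) to zero across a 1-voxel soft shell
    return np.clip(radius + 0.5 - dist, 0.0, 1.0) * intensity


def generate_phantom(config: PhantomConfig, seed: int) -> Volume3D:
    """Generate a clean branching-tube phantom in [0, 1].

    Deterministic given ``(config, seed)``.  The foreground fraction (voxels
    above the background/tube-intensity midpoint) is reported in
    ``meta["foreground_fraction"]``.
    """
    shape = config.shape
    if min(shape) < 16:
        raise ValueError(f"each axis must be >= 16, got shape {shape}")
    if 2 * config.radius_range[1] + 1 > min(shape):
        raise ValueError(
            f"shape {shape} too small for maximum tube radius {config.radius_range[1]}")
    rng = np.random.default_rng(seed)
    vol = np.zeros(shape, dtype=np.float64)
    n_steps = int(1.5 * max(shape) / 0.5)

    def _place_tube(radius: float, intensity: float) -> np.ndarray:
        """Draw walks until the tube avoids existing ones (roots/vessels do
        not merge); accept the last attempt if separation keeps failing."""
        occupied = ndimage.binary_dilation(vol > 0)  # 1-voxel separation margin
        for _ in range(20):
            start = rng.uniform(low=[0, 0, 0], high=np.asarray(shape, dtype=float) - 1)
            pts = _walk_centerline(start, _random_unit(rng), n_steps,
                                   shape, config.curvature, rng)
            profile = _tube_profile(shape, pts, radius, intensity)
            if not np.any((profile > 0) & occupied):
                break
        np.maximum(vol, profile, out=vol)
        return pts

    for _ in range(config.n_tubes):
        radius = rng.uniform(*config.radius_range)
        intensity = rng.uniform(*config.tube_intensity_range)
        pts = _place_tube(radius, intensity)
        if rng.uniform() < config.branch_prob and len(pts) > 2:
            origin = pts[rng.integers(1, len(pts) - 1)]
            pts_b = _walk_centerline(origin, _random_unit(rng), n_steps // 2, shape,
                                     config.curvature, rng)
            profile = _tube_profile(shape, pts_b, max(0.5, 0.7 * radius), intensity)
            np.maximum(vol, profile, out=vol)
    vol = np.clip(np.maximum(vol, config.background_level), 0.0, 1.0)
    thr = 0.5 * (config.background_level + config.tube_intensity_range[0])
    fg = float(np.mean(vol > thr))
    return Volume3D(vol.astype(np.float32), meta={"foreground_fraction": fg})


def add_rician_noise(vol: Volume3D, noise: NoiseSpec, peak: float | None = None) -> Volume3D:
    """Corrupt a normalized volume with Rician noise.

    sigma = ``noise.level`` x peak intensity; ``peak`` defaults to the volume
    maximum (1.0 for an all-zero volume, so pure-noise backgrounds are
    well defined).  Deterministic given ``noise.seed``; output is nonnegative
    with E[out^2] = A^2 + 2 sigma^2 per voxel of amplitude A.
    """
    m = vol.max()
    if m > 1.0 + 1e-6:
        raise ValueError(
            f"input must be normalized to [0, 1] (max intensity {m:.4g}); "
            "apply normalize_intensity first")
    if noise.level == 0:
        return vol.copy()
    if peak is None:
        peak = m if m > 0 else 1.0
    sigma = noise.level * peak
    rng = np.random.default_rng(noise.seed)
    g1 = rng.normal(0.0, sigma, size=vol.shape)
    g2 = rng.normal(0.0, sigma, size=vol.shape)
    out = np.sqrt((vol.data + g1) ** 2 + g2 ** 2)
    meta = dict(vol.meta)
    meta.update(noise_level=noise.level, noise_sigma=sigma)
    return Volume3D(out.astype(np.float32), vol.spacing, meta)
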
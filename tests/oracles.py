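"""Independent brute-force reference implementations used only by the tests.

Everything here is written with explicit nested loops (or scalar formulas) on
tiny inputs, deliberately sharing no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def conv3d_loops(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """Same-padding stride-1 3D cross-correlation, scalar loops. x: (C,D,H,W)."""
    O, C, kd, kh, kw = w.shape
    _, D, H, W = x.shape
    rd, rh, rw = kd // 2, kh // 2, kw // 2
    out = np.zeros((O, D, H, W))
    for o in range(O):
        for z in range(D):
            for y in range(H):
                for xx in range(W):
                    acc = 0.0
                    for c in range(C):
                        for i in range(kd):
                            for j in range(kh):
                                for k in range(kw):
                                    zz, yy, xz = z + i - rd, y + j - rh, xx + k - rw
                                    if 0 <= zz < D and 0 <= yy < H and 0 <= xz < W:
                                        acc += x[c, zz, yy, xz] * w[o, c, i, j, k]
                    out[o, z, y, xx] = acc + (b[o] if b is not None else 0.0)
    return out


def perceptual_loss_loops(layer_weights: list[tuple[np.ndarray, np.ndarray | None]],
                          pred: np.ndarray, target: np.ndarray) -> float:
    """Layer-wise normalized squared feature distance, all by nested loops.

    ``layer_weights``: per conv layer (weight, bias); ReLU after each layer.
    ``pred``/``target``: (D, H, W) arrays.
    """
    total = 0.0
    fp, ft = pred[None].astype(np.float64), target[None].astype(np.float64)
    for w, b in layer_weights:
        fp = np.maximum(conv3d_loops(fp, w.astype(np.float64),
                                     None if b is None else b.astype(np.float64)), 0.0)
        ft = np.maximum(conv3d_loops(ft, w.astype(np.float64),
                                     None if b is None else b.astype(np.float64)), 0.0)
        sq = 0.0
        n = 0
        for c in range(fp.shape[0]):
            for z in range(fp.shape[1]):
                for y in range(fp.shape[2]):
                    for x in range(fp.shape[3]):
                        d = fp[c, z, y, x] - ft[c, z, y, x]
                        sq += d * d
                        n += 1
        total += sq / n
    return total


def ssim3d_loops(a: np.ndarray, b: np.ndarray, data_range: float = 1.0,
                 win: int = 11, sigma: float = 1.5) -> float:
    """Sliding-window Gaussian SSIM over every position where the window fits."""
    r = win // 2
    g1 = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
    g1 /= g1.sum()
    kernel = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    D, H, W = a.shape
    vals = []
    for z in range(r, D - r):
        for y in range(r, H - r):
            for x in range(r, W - r):
                pa = a[z - r:z + r + 1, y - r:y + r + 1, x - r:x + r + 1]
                pb = b[z - r:z + r + 1, y - r:y + r + 1, x - r:x + r + 1]
                mu_a = (kernel * pa).sum()
                mu_b = (kernel * pb).sum()
                var_a = (kernel * pa * pa).sum() - mu_a ** 2
                var_b = (kernel * pb * pb).sum() - mu_b ** 2
                cov = (kernel * pa * pb).sum() - mu_a * mu_b
                vals.append(((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                            / ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)))
    return float(np.mean(vals))


def mean_abs_loops(a: np.ndarray, b: np.ndarray) -> float:
    acc = 0.0
    for av, bv in zip(a.ravel(), b.ravel()):
        acc += abs(float(av) - float(bv))
    return acc / a.size


def mse_loops(a: np.ndarray, b: np.ndarray) -> float:
    acc = 0.0
    for av, bv in zip(a.ravel(), b.ravel()):
        acc += (float(av) - float(bv)) ** 2
    return acc / a.size


def rayleigh_mean(sigma: float) -> float:
    return sigma * math.sqrt(math.pi / 2.0)
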
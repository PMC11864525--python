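"""Training objectives: untrained perceptual loss, L1, and SSIM loss.

The perceptual loss between a prediction y_hat and ground truth y under a
feature extractor phi with tap points j is

    PL = sum_j  1/(C_j H_j W_j D_j) * || phi_j(y_hat) - phi_j(y) ||_2^2

i.e. the squared Frobenius norm of the per-layer feature difference,
normalized by the layer's entry count.  With a frozen random extractor this
is the *untrained* perceptual loss: gradients flow to the prediction only,
never to phi.  Batched inputs average the per-volume loss over the batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .loss_networks import FeatureExtractor
from .nn import Tensor
from .volume import Volume3D

__all__ = ["FeatureMaps", "LossValue", "extract_features", "perceptual_loss",
           "l1_loss", "ssim_objective"]


def _lift(x, requires_grad: bool = False) -> Tensor:
    """Coerce Volume3D / 3D / 4D / 5D array (or Tensor) to a (B,1,D,H,W) Tensor."""
    if isinstance(x, Tensor):
        if x.ndim == 3:
            return x.reshape((1, 1) + x.shape)
        if x.ndim == 5:
            return x
        raise ValueError(f"expected a 3D or 5D tensor, got rank {x.ndim}")
    if isinstance(x, Volume3D):
        x = x.data
    arr = np.asarray(x, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None, None]
    elif arr.ndim == 4:  # (B, D, H, W)
        arr = arr[:, None]
    elif arr.ndim != 5:
        raise ValueError(f"expected a 3D/4D/5D array, got rank {arr.ndim}")
    return Tensor(arr, requires_grad=requires_grad)


def _check_same_shape(a: Tensor, b: Tensor) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


@dataclass
class FeatureMaps:
    """Per-layer activations of an extractor, with dims recorded per layer."""

    maps: list[np.ndarray]
    dims: list[tuple[int, ...]]  # per layer: (C, D, H, W) spatial record

    def __len__(self) -> int:
        return len(self.maps)


@dataclass
class LossValue:
    """A nonnegative scalar loss with its per-layer contributions.

    ``tensor`` is the autodiff node (call ``tensor.backward()`` to get
    gradients with respect to the prediction).
    """

    value: float
    per_layer: list[float]
    tensor: Tensor


def extract_features(extractor: FeatureExtractor, vol) -> FeatureMaps:
    """Run ``vol`` (Volume3D or batch) through the frozen extractor.

    Returns the activations detached from any graph; extractor parameters are
    untouched.  Single volumes yield (C, D, H, W) maps, batches keep the
    batch axis.
    """
    single = isinstance(vol, Volume3D) or (
        not isinstance(vol, Tensor) and np.asarray(vol).ndim == 3)
    x = _lift(vol)
    taps = extractor(Tensor(x.data))
    maps = [t.data[0] if single else t.data for t in taps]
    dims = [tuple(t.shape[1:]) for t in taps]
    return FeatureMaps(maps=maps, dims=dims)


def perceptual_loss(extractor: FeatureExtractor, pred, target) -> LossValue:
    """Untrained perceptual loss between ``pred`` and ``target``.

    Differentiable with respect to ``pred`` (pass a Tensor with
    ``requires_grad=True`` or read gradients via ``LossValue.tensor``); the
    extractor receives no gradient.  Batches average over the batch axis.
    """
    p = _lift(pred, requires_grad=not isinstance(pred, Tensor))
    t = _lift(target)
    _check_same_shape(p, t)
    taps_p = extractor(p)
    taps_t = extractor(t.detach())
    contribs = []
    for fp, ft in zip(taps_p, taps_t):
        d = fp - ft.detach()
        contribs.append((d * d).mean())  # == ||.||^2 / (C*D*H*W), batch-averaged
    total = contribs[0]
    for c in contribs[1:]:
        total = total + c
    return LossValue(value=total.item(),
                     per_layer=[c.item() for c in contribs],
                     tensor=total)


def l1_loss(pred, target):
    """Mean absolute voxel difference.  Returns a Tensor for Tensor inputs."""
    tensor_in = isinstance(pred, Tensor) or isinstance(target, Tensor)
    p, t = _lift(pred), _lift(target)
    _check_same_shape(p, t)
    out = (p - t.detach()).abs().mean()
    return out if tensor_in else out.item()


def ssim_objective(pred, target, data_range: float = 1.0):
    """1 - SSIM3D(pred, target): minimizing it maximizes structural similarity.

    Lies in [0, 2]; differentiable.  Uses the same Gaussian-window SSIM as
    :func:`uperc3d.metrics.ssim3d` (sigma 1.5, window 11 where it fits), so
    the two agree to numerical precision.  Returns a Tensor for Tensor inputs.
    """
    from .metrics import gaussian_kernel1d, ssim_window_size

    tensor_in = isinstance(pred, Tensor) or isinstance(target, Tensor)
    p, t = _lift(pred), _lift(target)
    _check_same_shape(p, t)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    win = ssim_window_size(p.shape[2:])
    kernel = gaussian_kernel1d(win)
    p64 = p.astype(np.float64)
    t64 = t.detach().astype(np.float64)

    from .nn import functional as F

    def blur(x: Tensor) -> Tensor:
        k = kernel.astype(np.float64)
        for ax, shape in enumerate([(1, 1, win, 1, 1), (1, 1, 1, win, 1), (1, 1, 1, 1, win)]):
            x = F.conv3d(x, Tensor(k.reshape(shape)), None, padding="valid")
        return x

    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_p, mu_t = blur(p64), blur(t64)
    var_p = blur(p64 * p64) - mu_p * mu_p
    var_t = blur(t64 * t64) - mu_t * mu_t
    cov = blur(p64 * t64) - mu_p * mu_t
    num = (2.0 * mu_p * mu_t + c1) * (2.0 * cov + c2)
    den = (mu_p * mu_p + mu_t * mu_t + c1) * (var_p + var_t + c2)
    ssim = (num / den).mean()
    out = (1.0 - ssim).astype(np.float32)
    return out if tensor_in else out.item()
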
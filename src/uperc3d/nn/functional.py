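"""Neural-network primitives on the autodiff engine.

3D convolution is lowered to a single GEMM per layer (im2col), which is the
only way CPU training of the volumetric networks stays tractable.  All
functions accept and return :class:`~uperc3d.nn.autodiff.Tensor`.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Tensor

__all__ = ["conv3d", "max_pool3d", "softmax", "l2_normalize"]


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, (tuple, list)):
        if len(v) != 3:
            raise ValueError("expected 3 values")
        return tuple(int(x) for x in v)
    return (int(v),) * 3


def _im2col(arr: np.ndarray, kernel: tuple[int, int, int],
            stride: tuple[int, int, int]) -> tuple[np.ndarray, tuple[int, int, int]]:
    """(B, C, D, H, W) -> ((B*L, C*k^3) patch matrix, output spatial dims)."""
    win = sliding_window_view(arr, kernel, axis=(2, 3, 4))
    win = win[:, :, ::stride[0], ::stride[1], ::stride[2]]
    B, C = arr.shape[:2]
    Do, Ho, Wo = win.shape[2:5]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7))
    return cols.reshape(B * Do * Ho * Wo, C * kernel[0] * kernel[1] * kernel[2]), (Do, Ho, Wo)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride=1, padding="same") -> Tensor:
    """3D cross-correlation over a (B, C, D, H, W) batch.

    ``padding`` is "same" (stride-1 shape-preserving), "valid", or an integer /
    triple of zeros added per side.  Raises ``ValueError`` when the padded
    input is smaller than the kernel.
    """
    if x.ndim != 5:
        raise ValueError(f"conv3d expects a 5D (B,C,D,H,W) input, got rank {x.ndim}")
    O, C, kd, kh, kw = weight.shape
    if x.shape[1] != C:
        raise ValueError(f"input has {x.shape[1]} channels, weight expects {C}")
    sd, sh, sw = _triple(stride)
    if padding == "same":
        if (sd, sh, sw) != (1, 1, 1):
            raise ValueError("'same' padding requires stride 1")
        pd, ph, pw = kd // 2, kh // 2, kw // 2
    elif padding == "valid":
        pd = ph = pw = 0
    else:
        pd, ph, pw = _triple(padding)

    B = x.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw))) \
        if (pd or ph or pw) else x.data
    Di, Hi, Wi = xp.shape[2:]
    if Di < kd or Hi < kh or Wi < kw:
        raise ValueError(
            f"input spatial size {xp.shape[2:]} smaller than kernel {(kd, kh, kw)}")
    cols, (Do, Ho, Wo) = _im2col(xp, (kd, kh, kw), (sd, sh, sw))
    L = Do * Ho * Wo
    K = C * kd * kh * kw
    wmat = weight.data.reshape(O, K)
    out = cols @ wmat.T
    if bias is not None:
        out += bias.data
    out = np.ascontiguousarray(out.reshape(B, Do, Ho, Wo, O).transpose(0, 4, 1, 2, 3))

    parents = (x, weight) if bias is None else (x, weight, bias)
    if not weight.requires_grad:
        cols = None  # frozen layer: no dW, drop the im2col buffer

    def bwd(g):
        gmat = None
        if (bias is not None and bias.requires_grad) or weight.requires_grad:
            gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(B * L, O)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=0))
        if weight.requires_grad:
            weight._accumulate((gmat.T @ cols).reshape(weight.shape))
        if x.requires_grad:
            stride1 = (sd, sh, sw) == (1, 1, 1)
            if stride1 and pd <= kd - 1 and ph <= kh - 1 and pw <= kw - 1:
                # transposed conv as one GEMM: full-correlate g with the
                # spatially flipped, channel-swapped kernel
                gp = np.pad(g, ((0, 0), (0, 0), (kd - 1 - pd,) * 2,
                                (kh - 1 - ph,) * 2, (kw - 1 - pw,) * 2))
                gcols, _ = _im2col(gp, (kd, kh, kw), (1, 1, 1))
                wflip = np.ascontiguousarray(
                    weight.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
                ).reshape(C, O * kd * kh * kw)
                dx = (gcols @ wflip.T).reshape(x.shape[0], x.shape[2], x.shape[3],
                                               x.shape[4], C)
                x._accumulate(np.ascontiguousarray(dx.transpose(0, 4, 1, 2, 3)))
            else:  # strided / heavily padded: scatter-add per kernel tap
                if gmat is None:
                    gmat = np.ascontiguousarray(
                        g.transpose(0, 2, 3, 4, 1)).reshape(B * L, O)
                dcols = (gmat @ wmat).reshape(B, Do, Ho, Wo, C, kd, kh, kw)
                dcols = dcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)
                dxp = np.zeros_like(xp)
                for i in range(kd):
                    for j in range(kh):
                        for k in range(kw):
                            dxp[:, :, i:i + Do * sd:sd, j:j + Ho * sh:sh,
                                k:k + Wo * sw:sw] += dcols[..., i, j, k]
                if pd or ph or pw:
                    dxp = dxp[:, :, pd:pd + x.shape[2], ph:ph + x.shape[3],
                              pw:pw + x.shape[4]]
                x._accumulate(dxp)

    return Tensor._make(out, parents, bwd)


def max_pool3d(x: Tensor, kernel=2, stride=None) -> Tensor:
    """3D max pooling, floor (valid) semantics on non-divisible axes."""
    if x.ndim != 5:
        raise ValueError(f"max_pool3d expects a 5D input, got rank {x.ndim}")
    kd, kh, kw = _triple(kernel)
    sd, sh, sw = _triple(stride if stride is not None else kernel)
    B, C, Di, Hi, Wi = x.shape
    if Di < kd or Hi < kh or Wi < kw:
        raise ValueError(
            f"input spatial size {(Di, Hi, Wi)} smaller than pooling window {(kd, kh, kw)}")
    win = sliding_window_view(x.data, (kd, kh, kw), axis=(2, 3, 4))[:, :, ::sd, ::sh, ::sw]
    Do, Ho, Wo = win.shape[2:5]
    cols = np.ascontiguousarray(win).reshape(B, C, Do, Ho, Wo, kd * kh * kw)
    idx = cols.argmax(axis=-1)
    out = np.take_along_axis(cols, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        dz, rem = np.divmod(idx, kh * kw)
        dy, dx = np.divmod(rem, kw)
        bi, ci, di, hi, wi = np.indices((B, C, Do, Ho, Wo), sparse=True)
        dxp = np.zeros_like(x.data)
        np.add.at(dxp, (bi, ci, di * sd + dz, hi * sh + dy, wi * sw + dx), g)
        x._accumulate(dxp)

    return Tensor._make(out, (x,), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    norm = ((x * x).sum(axis=axis, keepdims=True) + eps).sqrt()
    return x / norm
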
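"""Frozen, randomly initialized 3D feature extractors for the perceptual loss.

The untrained perceptual loss compares feature maps of a *random* network
that is never optimized: its weights are drawn once from a named scheme and
stay fixed for the whole denoiser training run.  The module covers the full
ablation space — depth (3/5/7/9/13 conv layers), kernel size (3/5/7/9),
channel width, max-pooling positions, five initialization schemes — plus 3D
translations of the VGG19 and AlexNet convolutional stacks as presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["LossNetConfig", "FeatureExtractor", "build_loss_network",
           "initialize_weights", "build_preset_vgg19_3d", "build_preset_alexnet_3d"]

PRESETS = ("simple", "vgg19_3d", "alexnet_3d")
SIMPLE_DEPTHS = (3, 5, 7, 9, 13)
SIMPLE_KERNELS = (3, 5, 7, 9)


@dataclass
class LossNetConfig:
    """Configuration of one untrained feature extractor.

    For the ``simple`` preset: ``depth`` conv layers (same padding, stride 1,
    ``n_features`` channels each) joined by ReLU, with a window-2 max pool
    inserted after each layer index listed in ``pooling_after`` (1-based).
    ``init_method`` names one of the five schemes in :mod:`uperc3d.nn.init`;
    ``seed`` makes the draw reproducible.  ``layer_mask`` optionally restricts
    which activation taps enter the loss (default: all).
    """

    preset: str = "simple"
    depth: int = 3
    kernel_size: int = 3
    n_features: int = 32
    pooling_after: tuple[int, ...] = ()
    init_method: str = "xavier_normal"
    seed: int = 0
    legacy_sqrt_bound: bool = False
    layer_mask: tuple[int, ...] | None = None
    max_taps: int | None = 8  # presets only: cap on exposed activations

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; valid: {PRESETS}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd, got {self.kernel_size}")
        self.pooling_after = tuple(sorted(int(i) for i in self.pooling_after))
        for i in self.pooling_after:
            if not 1 <= i <= self.depth:
                raise ValueError(
                    f"pooling_after index {i} out of range 1..{self.depth}")
        if self.init_method not in nn.INIT_METHODS:
            raise ValueError(
                f"unknown init method {self.init_method!r}; "
                f"valid methods: {', '.join(nn.INIT_METHODS)}")


class FeatureExtractor(nn.Module):
    """Frozen stack of conv/activation/pool layers with tap points.

    ``forward`` returns the list of activation outputs (one per tap).  All
    parameters are excluded from optimization; they must be bit-identical
    before and after any surrounding training run.
    """

    def __init__(self, layers: list[nn.Module], tap_layer_indices: list[int],
                 config: LossNetConfig | None = None, min_input: int = 1):
        super().__init__()
        self.layers = layers
        self.tap_layer_indices = list(tap_layer_indices)
        self.config = config
        self.min_input = min_input
        self.frozen = True
        self.eval()
        self.freeze()

    @property
    def n_taps(self) -> int:
        return len(self.tap_layer_indices)

    def forward(self, x: Tensor) -> list[Tensor]:
        if x.ndim != 5:
            raise ValueError(f"expected a 5D (B,C,D,H,W) input, got rank {x.ndim}")
        if min(x.shape[2:]) < self.min_input:
            raise ValueError(
                f"input spatial size {x.shape[2:]} below this extractor's "
                f"minimum {self.min_input}")
        taps = []
        last = max(self.tap_layer_indices)
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i in self.tap_layer_indices:
                taps.append(x)
            if i >= last:
                break
        return taps

    def checksum(self) -> float:
        """Order-stable sum over all parameters (frozen-contract checks)."""
        return float(sum(np.float64(p.data).sum() for p in self.parameters()))


def build_loss_network(config: LossNetConfig) -> FeatureExtractor:
    """Build the extractor described by ``config`` (frozen, deterministic)."""
    if config.preset == "vgg19_3d":
        return build_preset_vgg19_3d(config.seed, max_taps=config.max_taps)
    if config.preset == "alexnet_3d":
        return build_preset_alexnet_3d(config.seed, max_taps=config.max_taps)
    rng = np.random.default_rng(config.seed)
    layers: list[nn.Module] = []
    taps: list[int] = []
    in_ch = 1
    for d in range(1, config.depth + 1):
        layers.append(nn.Conv3d(in_ch, config.n_features, config.kernel_size,
                                padding="same", rng=rng))
        layers.append(nn.ReLU())
        taps.append(len(layers) - 1)
        if d in config.pooling_after:
            layers.append(nn.MaxPool3d(2, 2))
        in_ch = config.n_features
    ex = FeatureExtractor(layers, taps, config=config,
                          min_input=2 ** len(config.pooling_after))
    initialize_weights(ex, config.init_method, config.seed,
                       legacy_sqrt_bound=config.legacy_sqrt_bound)
    if config.layer_mask is not None:
        ex.tap_layer_indices = [ex.tap_layer_indices[i] for i in config.layer_mask]
    return ex


def initialize_weights(extractor: FeatureExtractor, method: str, seed: int,
                       legacy_sqrt_bound: bool = False) -> FeatureExtractor:
    """(Re-)draw every conv weight of ``extractor`` from ``method``; frozen after."""
    nn.init_module(extractor, method, seed, legacy_sqrt_bound=legacy_sqrt_bound)
    extractor.freeze()
    return extractor


# VGG19 conv stack: channel progression with 'P' marking 2x max pools.
_VGG19_PLAN = (64, 64, "P", 128, 128, "P", 256, 256, 256, 256, "P",
               512, 512, 512, 512, "P", 512, 512, 512, 512, "P")


def build_preset_vgg19_3d(seed: int, max_taps: int | None = 8) -> FeatureExtractor:
    """3D translation of the VGG19 convolutional stack (untrained, frozen).

    2D 3x3 convs become 3x3x3 convs with the channel progression unchanged;
    2D max pools become window-2 3D max pools.  Tap points sit at each ReLU;
    ``max_taps`` caps how many early activations are exposed (None = all 16),
    and layers beyond the last tap are not built.
    """
    rng = np.random.default_rng(seed)
    layers: list[nn.Module] = []
    taps: list[int] = []
    in_ch = 1
    n_pools = 0
    for item in _VGG19_PLAN:
        if item == "P":
            layers.append(nn.MaxPool3d(2, 2))
            n_pools += 1
            continue
        layers.append(nn.Conv3d(in_ch, item, 3, padding="same", rng=rng))
        layers.append(nn.ReLU())
        taps.append(len(layers) - 1)
        in_ch = item
        if max_taps is not None and len(taps) >= max_taps:
            break
    pools_before_last = sum(1 for l in layers[:max(taps)] if isinstance(l, nn.MaxPool3d))
    return FeatureExtractor(layers, taps, min_input=2 ** pools_before_last or 1)


def build_preset_alexnet_3d(seed: int, max_taps: int | None = 8) -> FeatureExtractor:
    """3D translation of the AlexNet convolutional stack (untrained, frozen).

    Channels 64, 192, 384, 256, 256; the strided 11-kernel first conv and the
    3/2 max pools are translated to 3D.  Inputs smaller than the stack's
    receptive footprint raise a dimensionality error on forward.
    """
    rng = np.random.default_rng(seed)
    layers: list[nn.Module] = [
        nn.Conv3d(1, 64, 11, stride=4, padding=2, rng=rng), nn.ReLU(),
        nn.MaxPool3d(3, 2),
        nn.Conv3d(64, 192, 5, padding=2, rng=rng), nn.ReLU(),
        nn.MaxPool3d(3, 2),
        nn.Conv3d(192, 384, 3, padding=1, rng=rng), nn.ReLU(),
        nn.Conv3d(384, 256, 3, padding=1, rng=rng), nn.ReLU(),
        nn.Conv3d(256, 256, 3, padding=1, rng=rng), nn.ReLU(),
        nn.MaxPool3d(3, 2),
    ]
    taps = [i for i, l in enumerate(layers) if isinstance(l, nn.ReLU)]
    if max_taps is not None:
        taps = taps[:max_taps]
    # smallest input edge that keeps every spatial dim >= 1 up to the last tap
    last = max(taps)
    min_input = 31 if last >= 7 else (15 if last >= 4 else 7)
    return FeatureExtractor(layers, taps, min_input=min_input)
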
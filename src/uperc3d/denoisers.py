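"""The three 3D denoising architectures: DnCNN, ResNet, and a sequential
channel-attention transformer.

All three map a (B, 1, D, H, W) volume to a same-shaped output.

* DnCNN: head conv (64 ch, kernel 3) + ReLU; three blocks of conv + ReLU +
  batch norm; tail conv to 1 channel — exactly five convolutions at defaults.
* ResNet: head conv + PReLU; five residual blocks (conv + batch norm + PReLU,
  identity skip around each block); tail conv + batch norm + PReLU; final
  1-channel projection.
* Transformer: head conv (8 ch, kernel 3); N sequential blocks of
  [channel attention (MDTA) -> gated feed-forward], no spatial down/up
  sampling; 1-channel tail conv.  MDTA flattens space to length L = D*H*W,
  L2-normalizes each channel's spatial vector and applies softmax attention
  over a channels x channels matrix (cost quadratic in channels, linear in
  voxels), scaled by a learnable temperature.

``residual_output=True`` makes a network predict the noise and return
input - prediction instead of the image directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, functional as F

__all__ = ["DenoiserConfig", "build_denoiser", "build_dncnn", "build_resnet",
           "build_transformer3d", "DnCNN", "ResNet3d", "Transformer3d"]

ARCHITECTURES = ("dncnn", "resnet", "transformer")


@dataclass
class DenoiserConfig:
    """Architecture choice plus hyper-parameters (defaults as described above)."""

    architecture: str = "dncnn"
    dncnn_channels: int = 64
    dncnn_blocks: int = 3
    resnet_channels: int = 64
    resnet_blocks: int = 5
    transformer_channels: int = 8
    transformer_ff: tuple[int, int] = (16, 32)
    transformer_blocks: int = 4
    transformer_heads: int = 1
    residual_output: bool = False

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; valid: {ARCHITECTURES}")
        for name in ("dncnn_channels", "resnet_channels", "transformer_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        self.transformer_ff = tuple(int(c) for c in self.transformer_ff)
        if len(self.transformer_ff) != 2:
            raise ValueError("transformer_ff must be an ordered pair")
        if self.transformer_channels % self.transformer_heads != 0:
            raise ValueError("transformer_channels must divide evenly over heads")


class _ResidualWrapper(nn.Module):
    """Optionally turn a network into a noise predictor: out = x - f(x)."""

    def __init__(self, body: nn.Module, residual_output: bool):
        super().__init__()
        self.body = body
        self.residual_output = residual_output

    def forward(self, x: Tensor) -> Tensor:
        y = self.body(x)
        return x - y if self.residual_output else y


class DnCNN(nn.Module):
    def __init__(self, config: DenoiserConfig, rng: np.random.Generator):
        super().__init__()
        ch = config.dncnn_channels
        layers: list[nn.Module] = [nn.Conv3d(1, ch, 3, padding="same", rng=rng),
                                   nn.ReLU()]
        for _ in range(config.dncnn_blocks):
            layers += [nn.Conv3d(ch, ch, 3, padding="same", rng=rng),
                       nn.ReLU(), nn.BatchNorm3d(ch)]
        layers.append(nn.Conv3d(ch, 1, 3, padding="same", rng=rng))
        self.net = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)

    @property
    def conv_layers(self) -> list[nn.Conv3d]:
        return [l for l in self.net if isinstance(l, nn.Conv3d)]


class _ResBlock(nn.Module):
    """conv -> batch norm -> PReLU with an additive identity skip."""

    def __init__(self, ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv3d(ch, ch, 3, padding="same", rng=rng)
        self.bn = nn.BatchNorm3d(ch)
        self.act = nn.PReLU()

    def forward(self, x: Tensor) -> Tensor:
        return x + self.act(self.bn(self.conv(x)))


class ResNet3d(nn.Module):
    def __init__(self, config: DenoiserConfig, rng: np.random.Generator):
        super().__init__()
        ch = config.resnet_channels
        self.head = nn.Sequential(nn.Conv3d(1, ch, 3, padding="same", rng=rng),
                                  nn.PReLU())
        self.blocks = [_ResBlock(ch, rng) for _ in range(config.resnet_blocks)]
        self.tail = nn.Sequential(nn.Conv3d(ch, ch, 3, padding="same", rng=rng),
                                  nn.BatchNorm3d(ch), nn.PReLU())
        self.proj = nn.Conv3d(ch, 1, 3, padding="same", rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.head(x)
        for blk in self.blocks:
            x = blk(x)
        return self.proj(self.tail(x))


class MDTA(nn.Module):
    """Multi-head transposed (channel) attention.

    Queries/keys/values come from 1x1x1 convolutions; spatial dims are
    flattened to length L and attention is computed over the channel axis:
    softmax(temperature * q_hat k_hat^T) with L2-normalized channel vectors.
    The last attention matrix is kept (detached) for inspection.
    """

    def __init__(self, ch: int, heads: int, rng: np.random.Generator):
        super().__init__()
        self.ch = ch
        self.heads = heads
        self.q = nn.Conv3d(ch, ch, 1, padding="valid", rng=rng)
        self.k = nn.Conv3d(ch, ch, 1, padding="valid", rng=rng)
        self.v = nn.Conv3d(ch, ch, 1, padding="valid", rng=rng)
        self.proj = nn.Conv3d(ch, ch, 1, padding="valid", rng=rng)
        self.temperature = nn.Parameter(np.ones(1))
        self.last_attention: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        B, C, D, H, W = x.shape
        L = D * H * W
        hd = C // self.heads

        def heads_view(t: Tensor) -> Tensor:
            return t.reshape((B, self.heads, hd, L))

        q = F.l2_normalize(heads_view(self.q(x)), axis=-1)
        k = F.l2_normalize(heads_view(self.k(x)), axis=-1)
        v = heads_view(self.v(x))
        attn = F.softmax((q @ k.transpose((0, 1, 3, 2))) * self.temperature, axis=-1)
        self.last_attention = attn.data.copy()
        out = (attn @ v).reshape((B, C, D, H, W))
        return x + self.proj(out)


class _GatedFF(nn.Module):
    """Two expanding convs; the expanded half-pairs gate each other
    elementwise, then a 1x1x1 conv projects back to the block width."""

    def __init__(self, ch: int, ff: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv3d(ch, ff[0], 3, padding="same", rng=rng)
        self.conv2 = nn.Conv3d(ff[0], ff[1], 3, padding="same", rng=rng)
        self.proj = nn.Conv3d(ff[1] // 2, ch, 1, padding="valid", rng=rng)
        self.half = ff[1] // 2

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv2(self.conv1(x).relu())
        gate = h[:, :self.half] * h[:, self.half:]
        return x + self.proj(gate)


class Transformer3d(nn.Module):
    def __init__(self, config: DenoiserConfig, rng: np.random.Generator):
        super().__init__()
        ch = config.transformer_channels
        self.head = nn.Conv3d(1, ch, 3, padding="same", rng=rng)
        blocks: list[nn.Module] = []
        for _ in range(config.transformer_blocks):
            blocks.append(MDTA(ch, config.transformer_heads, rng))
            blocks.append(_GatedFF(ch, config.transformer_ff, rng))
        self.blocks = blocks
        self.tail = nn.Conv3d(ch, 1, 3, padding="same", rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.head(x)
        for blk in self.blocks:
            x = blk(x)
        return self.tail(x)

    @property
    def attention_blocks(self) -> list[MDTA]:
        return [b for b in self.blocks if isinstance(b, MDTA)]


def build_dncnn(config: DenoiserConfig | None = None, seed: int = 0) -> nn.Module:
    config = config or DenoiserConfig(architecture="dncnn")
    return _ResidualWrapper(DnCNN(config, np.random.default_rng(seed)),
                            config.residual_output)


def build_resnet(config: DenoiserConfig | None = None, seed: int = 0) -> nn.Module:
    config = config or DenoiserConfig(architecture="resnet")
    return _ResidualWrapper(ResNet3d(config, np.random.default_rng(seed)),
                            config.residual_output)


def build_transformer3d(config: DenoiserConfig | None = None, seed: int = 0) -> nn.Module:
    config = config or DenoiserConfig(architecture="transformer")
    return _ResidualWrapper(Transformer3d(config, np.random.default_rng(seed)),
                            config.residual_output)


def build_denoiser(config: DenoiserConfig, seed: int = 0) -> nn.Module:
    builder = {"dncnn": build_dncnn, "resnet": build_resnet,
               "transformer": build_transformer3d}[config.architecture]
    model = builder(config, seed)
    model.config = config
    return model
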
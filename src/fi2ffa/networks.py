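"""Translation networks: dual-decoder U-shaped generator and PatchGAN critics.

The generator is a U-Net: an encoder of convolution blocks with 2x2
max-pooling, and a primary decoder of transposed convolutions with encoder
skip connections that emits the translated image (tanh head, [-1, 1]). A
mirrored *auxiliary decoder* reuses the same design to emit a vessel
structure raster (sigmoid head, [0, 1]); at each resolution it concatenates
its own upsampled features with the primary decoder's features at that
resolution. Information flows only from the primary path into the auxiliary
branch, never back: the image output has exactly zero gradient with respect
to branch-only parameters.

Discriminators are PatchGAN critics: fully-convolutional stacks of 4x4
convolutions (instance norm, leaky ReLU 0.2) mapping an input to a patch
score map with no output nonlinearity (the least-squares adversarial loss
operates on raw scores). Four are used during training: one each for real
vs fake FI, FFA, FI structure, and FFA structure.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "TranslationBundle",
    "UNetGenerator",
    "PatchDiscriminator",
    "build_generator",
    "build_discriminator",
    "count_parameters",
]


@dataclass
class GeneratorConfig:
    """Full-scale default (depth 7, 64 base channels); ``tiny()`` gives a
    CPU-friendly preset for small experiments."""

    in_channels: int = 3
    depth: int = 7
    base_channels: int = 64
    max_channels: int = 512
    out_image_channels: int = 3
    out_structure_channels: int = 1
    norm: str = "instance"

    @classmethod
    def tiny(cls, **kw) -> "GeneratorConfig":
        kw.setdefault("depth", 3)
        kw.setdefault("base_channels", 16)
        kw.setdefault("max_channels", 128)
        return cls(**kw)

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("generator depth must be >= 2")
        if self.base_channels < 8:
            raise ValueError("base_channels must be >= 8")
        if self.norm != "instance":
            raise ValueError("only instance normalization is supported")

    def channels(self, level: int) -> int:
        return min(self.base_channels * 2**level, self.max_channels)


@dataclass
class DiscriminatorConfig:
    in_channels: int = 3
    n_layers: int = 3
    base_channels: int = 64
    leaky_slope: float = 0.2
    # instance-norm statistics couple every pixel, so the patch locality of
    # the critic holds for its convolutional path; disabling the norm gives
    # a critic whose gradient footprint equals the conv receptive field
    use_norm: bool = True

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


@dataclass
class TranslationBundle:
    """Tensors of one translation direction (source x, fake, cycle)."""

    x: Tensor  # source image
    y_hat: Tensor  # translated image (fake target)
    s_hat: Tensor | None  # predicted structure of the source
    x_cyc: Tensor | None = None  # cyclically reconstructed source
    s_cyc: Tensor | None = None  # structure predicted during the cycle pass


class _ConvBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, rng, norm: bool = True):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 3, stride=1, padding=1, rng=rng)
        self.norm = nn.InstanceNorm2d(out_ch) if norm else None
        self.act = nn.LeakyReLU(0.2)

    def forward(self, x):
        x = self.conv(x)
        if self.norm is not None:
            x = self.norm(x)
        return self.act(x)


class UNetGenerator(nn.Module):
    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        d = cfg.depth
        chans = [cfg.channels(i) for i in range(d + 1)]  # encoder levels + bottleneck

        self.enc = nn.ModuleList(
            _ConvBlock(cfg.in_channels if i == 0 else chans[i - 1], chans[i], rng, norm=i > 0)
            for i in range(d)
        )
        self.pool = nn.MaxPool2d(2)
        self.bottleneck = _ConvBlock(chans[d - 1], chans[d], rng)

        # primary decoder: upsample, concat encoder skip, fuse
        self.up = nn.ModuleList(
            nn.ConvTranspose2d(chans[i + 1], chans[i], 2, stride=2, rng=rng) for i in reversed(range(d))
        )
        self.dec = nn.ModuleList(_ConvBlock(2 * chans[i], chans[i], rng) for i in reversed(range(d)))
        self.image_head = nn.Conv2d(chans[0], cfg.out_image_channels, 3, padding=1, rng=rng)

        # auxiliary decoder: same shape, skips come from the primary decoder
        self.aux_up = nn.ModuleList(
            nn.ConvTranspose2d(chans[i + 1], chans[i], 2, stride=2, rng=rng) for i in reversed(range(d))
        )
        self.aux_dec = nn.ModuleList(_ConvBlock(2 * chans[i], chans[i], rng) for i in reversed(range(d)))
        self.structure_head = nn.Conv2d(chans[0], cfg.out_structure_channels, 3, padding=1, rng=rng)

    def forward(self, x: Tensor, with_structure: bool = True):
        if not np.isfinite(x.data).all():
            raise ValueError("generator input contains non-finite values")
        n, c, h, w = x.shape
        if c != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} input channels, got {c}")
        if h % 2**self.cfg.depth or w % 2**self.cfg.depth:
            raise ValueError(f"input spatial size must be divisible by {2**self.cfg.depth}")

        skips = []
        h_t = x
        for blk in self.enc:
            h_t = blk(h_t)
            skips.append(h_t)
            h_t = self.pool(h_t)
        bott = self.bottleneck(h_t)

        dec_feats = []
        h_t = bott
        for up, blk, skip in zip(self.up, self.dec, reversed(skips)):
            h_t = up(h_t)
            h_t = blk(nn.concat([h_t, skip], axis=1))
            dec_feats.append(h_t)
        image = self.image_head(h_t).tanh()

        if not with_structure:
            return image, None
        a = bott
        for up, blk, feat in zip(self.aux_up, self.aux_dec, dec_feats):
            a = up(a)
            a = blk(nn.concat([a, feat], axis=1))
        structure = self.structure_head(a).sigmoid()
        return image, structure

    def primary_parameters(self):
        """Parameters of the encoder + primary decoder + image head."""
        for m in (self.enc, self.bottleneck, self.up, self.dec, self.image_head):
            yield from m.parameters()

    def auxiliary_parameters(self):
        """Parameters reachable only from the structure output."""
        for m in (self.aux_up, self.aux_dec, self.structure_head):
            yield from m.parameters()


class PatchDiscriminator(nn.Module):
    """Markovian patch critic: 4x4 convs, stride 2 except the last two."""

    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        layers: list[nn.Module] = [
            nn.Conv2d(cfg.in_channels, cfg.base_channels, 4, stride=2, padding=1, rng=rng),
            nn.LeakyReLU(cfg.leaky_slope),
        ]
        ch = cfg.base_channels
        for i in range(1, cfg.n_layers):
            out = min(cfg.base_channels * 2**i, cfg.base_channels * 8)
            layers.append(nn.Conv2d(ch, out, 4, stride=2, padding=1, rng=rng))
            if cfg.use_norm:
                layers.append(nn.InstanceNorm2d(out))
            layers.append(nn.LeakyReLU(cfg.leaky_slope))
            ch = out
        out = min(cfg.base_channels * 2**cfg.n_layers, cfg.base_channels * 8)
        layers.append(nn.Conv2d(ch, out, 4, stride=1, padding=1, rng=rng))
        if cfg.use_norm:
            layers.append(nn.InstanceNorm2d(out))
        layers.append(nn.LeakyReLU(cfg.leaky_slope))
        layers.append(nn.Conv2d(out, 1, 4, stride=1, padding=1, rng=rng))  # raw patch scores
        self.net = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)

    def receptive_field(self) -> int:
        """Effective receptive field of one output unit (standard recursion)."""
        specs = [(4, 2)] * self.cfg.n_layers + [(4, 1), (4, 1)]
        r, j = 1, 1
        for k, s in specs:
            r = r + (k - 1) * j
            j = j * s
        return r


def build_generator(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> UNetGenerator:
    return UNetGenerator(cfg, rng=rng)


def build_discriminator(cfg: DiscriminatorConfig, rng: np.random.Generator | None = None) -> PatchDiscriminator:
    return PatchDiscriminator(cfg, rng=rng)


def count_parameters(net: nn.Module) -> int:
    """Total trainable scalar parameters of a network."""
    return nn.count_parameters(net)
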
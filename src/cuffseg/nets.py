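"""Segmentation network: LinkNet-style encoder-decoder with optional
channel-attention skip gating and a DenseASPP bridge.

The architecture family is driven by :class:`ModelConfig`:

* a residual encoder (depth 18 or 34, block counts (2,2,2,2) / (3,4,6,3))
  whose stem (stride-2 conv + stride-2 max-pool) and four stages downsample
  by a total factor of 32, producing skip features at 1/4 (64 ch), 1/8
  (128 ch), 1/16 (256 ch) and a bottleneck at 1/32 (512 ch) — a 512-pixel
  input yields a 16 x 16 x 512 bottleneck;
* an optional squeeze-excitation gate on each skip connection, applied at
  the junction just before the additive fusion with the decoder feature;
* an optional densely connected atrous spatial pyramid (DenseASPP) bridging
  encoder and decoder: each dilated branch consumes the concatenation of
  the bottleneck with every previous branch output, and a final 1x1
  projection plus residual addition restores the bottleneck width;
* a LinkNet decoder (1x1 reduce -> 3x3 transposed conv stride 2 -> 1x1
  expand per block, additive skip fusion) ending in a transposed-conv head
  and a logistic pixel-probability map.

Five named variants reproduce the ablation grid: ``baseline`` (depth 18,
no extras), ``scheme1`` (depth 34), ``scheme2`` (+attention),
``scheme3`` (+DenseASPP), ``full`` (both).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeError
from .nn import functional as F

VARIANT_NAMES = ("baseline", "scheme1", "scheme2", "scheme3", "full")

#: channel widths of the four encoder stages (skips f1..f3 + bottleneck f4)
STAGE_CHANNELS = (64, 128, 256, 512)


@dataclass(frozen=True)
class ModelConfig:
    """Declarative description of one architecture variant."""

    encoder_depth: int = 34
    use_attention: bool = True
    use_denseaspp: bool = True
    attention_reduction: int = 16
    dilation_rates: tuple[int, ...] = (3, 6, 12, 18, 24)
    in_channels: int = 3
    out_channels: int = 1
    aspp_reduce: int = 128      # 1x1 bottleneck width inside each branch
    aspp_growth: int = 64       # channels each dense branch contributes

    def __post_init__(self):
        if self.encoder_depth not in (18, 34):
            raise ConfigurationError(
                f"encoder_depth must be 18 or 34, got {self.encoder_depth}")
        rates = tuple(self.dilation_rates)
        if any(r <= 0 for r in rates) or any(
                b <= a for a, b in zip(rates, rates[1:])):
            raise ConfigurationError(
                f"dilation_rates must be strictly increasing positive "
                f"integers, got {rates}")
        if self.attention_reduction < 1:
            raise ConfigurationError("attention_reduction must be positive")
        if self.use_attention:
            for c in STAGE_CHANNELS[:3]:
                if c % self.attention_reduction:
                    raise ConfigurationError(
                        f"attention_reduction {self.attention_reduction} must "
                        f"divide every gated channel count {STAGE_CHANNELS[:3]}")
        object.__setattr__(self, "dilation_rates", rates)


_VARIANTS: dict[str, ModelConfig] = {
    "baseline": ModelConfig(encoder_depth=18, use_attention=False, use_denseaspp=False),
    "scheme1": ModelConfig(encoder_depth=34, use_attention=False, use_denseaspp=False),
    "scheme2": ModelConfig(encoder_depth=34, use_attention=True, use_denseaspp=False),
    "scheme3": ModelConfig(encoder_depth=34, use_attention=False, use_denseaspp=True),
    "full": ModelConfig(encoder_depth=34, use_attention=True, use_denseaspp=True),
}


def build_variant(name: str) -> ModelConfig:
    """Map an ablation-variant name onto its :class:`ModelConfig`."""
    try:
        return _VARIANTS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown variant {name!r}; valid names: {', '.join(VARIANT_NAMES)}"
        ) from None


def _check_input_size(h: int, w: int) -> None:
    if h % 32 or w % 32:
        raise ShapeError(
            f"input spatial dims ({h} x {w}) must be divisible by 32: the "
            f"encoder downsamples by a total stride of 32")


class BasicBlock(nn.Module):
    """Two 3x3 convs with identity (or projected) residual."""

    def __init__(self, cin: int, cout: int, stride: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down = nn.Sequential(
                nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng),
                nn.BatchNorm2d(cout))
        else:
            self.down = nn.Identity()

    def forward(self, x):
        y = F.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        return F.relu(y + self.down(x))


class ResidualEncoder(nn.Module):
    """ResNet-18/34 style feature extractor exposing the four stage outputs."""

    BLOCK_COUNTS = {18: (2, 2, 2, 2), 34: (3, 4, 6, 3)}

    def __init__(self, depth: int, in_channels: int, rng):
        super().__init__()
        counts = self.BLOCK_COUNTS[depth]
        self.stem_conv = nn.Conv2d(in_channels, 64, 7, stride=2, padding=3,
                                   bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(64)
        self.pool = nn.MaxPool2d(3, 2, 1)
        cin = 64
        for idx, (cout, n_blocks) in enumerate(zip(STAGE_CHANNELS, counts)):
            stride = 1 if idx == 0 else 2
            blocks = [BasicBlock(cin, cout, stride, rng)]
            blocks += [BasicBlock(cout, cout, 1, rng) for _ in range(n_blocks - 1)]
            setattr(self, f"stage{idx + 1}", nn.Sequential(*blocks))
            cin = cout

    def forward(self, x):
        x = F.relu(self.stem_bn(self.stem_conv(x)))
        x = self.pool(x)
        f1 = self.stage1(x)
        f2 = self.stage2(f1)
        f3 = self.stage3(f2)
        f4 = self.stage4(f3)
        return f1, f2, f3, f4


class ChannelAttention(nn.Module):
    """Squeeze-excitation channel gate.

    Global average pooling squeezes each channel to a scalar; a two-layer
    bottleneck MLP (reduction ``r``) with a logistic output produces a gate
    in (0, 1) per channel, which rescales the input feature map.  Because
    every gate is strictly below 1, the output never exceeds the input in
    absolute value.
    """

    def __init__(self, channels: int, reduction: int = 16, rng=None):
        super().__init__()
        if channels % reduction:
            raise ConfigurationError(
                f"reduction {reduction} must divide channel count {channels}")
        rng = rng if rng is not None else np.random.default_rng()
        self.fc1 = nn.Linear(channels, channels // reduction, rng=rng)
        self.fc2 = nn.Linear(channels // reduction, channels, rng=rng)
        self.channels = channels

    def forward(self, x):
        n = x.shape[0]
        g = F.global_avg_pool(x)
        g = F.sigmoid(self.fc2(F.relu(self.fc1(g))))
        return x * g.reshape((n, self.channels, 1, 1))


class DenseASPP(nn.Module):
    """Densely connected atrous spatial pyramid over the bottleneck.

    Branch ``i`` sees the concatenation of the block input with the outputs
    of branches ``1..i-1``; each branch is a 1x1 channel reduction followed
    by a 3x3 dilated conv whose padding equals its dilation rate, so spatial
    dimensions never change.  A final 1x1 projection maps the full dense
    concatenation back to the input width and is added residually.
    """

    def __init__(self, channels: int, rates: Sequence[int],
                 reduce: int = 128, growth: int = 64, rng=None):
        super().__init__()
        rates = tuple(rates)
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise ConfigurationError("dilation rates must be ascending")
        rng = rng if rng is not None else np.random.default_rng()
        self.rates = rates
        self.branches = nn.ModuleList()
        cin = channels
        for d in rates:
            self.branches.append(nn.Sequential(
                nn.Conv2d(cin, reduce, 1, bias=False, rng=rng),
                nn.BatchNorm2d(reduce),
                nn.ReLU(),
                nn.Conv2d(reduce, growth, 3, padding=d, dilation=d,
                          bias=False, rng=rng),
                nn.BatchNorm2d(growth),
                nn.ReLU()))
            cin += growth
        self.project = nn.Conv2d(cin, channels, 1, bias=False, rng=rng)
        self.project_bn = nn.BatchNorm2d(channels)

    def forward(self, x):
        feats = [x]
        for branch in self.branches:
            inp = feats[0] if len(feats) == 1 else F.concat(feats, axis=1)
            feats.append(branch(inp))
        y = self.project_bn(self.project(F.concat(feats, axis=1)))
        return F.relu(x + y)


class DecoderBlock(nn.Module):
    """LinkNet decoder block: 1x1 reduce, 3x3 transposed conv x2, 1x1 expand."""

    def __init__(self, cin: int, cout: int, rng):
        super().__init__()
        mid = cin // 4
        self.reduce = nn.Conv2d(cin, mid, 1, bias=False, rng=rng)
        self.reduce_bn = nn.BatchNorm2d(mid)
        self.up = nn.ConvTranspose2d(mid, mid, 3, stride=2, padding=1,
                                     output_padding=1, bias=False, rng=rng)
        self.up_bn = nn.BatchNorm2d(mid)
        self.expand = nn.Conv2d(mid, cout, 1, bias=False, rng=rng)
        self.expand_bn = nn.BatchNorm2d(cout)

    def forward(self, x):
        x = F.relu(self.reduce_bn(self.reduce(x)))
        x = F.relu(self.up_bn(self.up(x)))
        return F.relu(self.expand_bn(self.expand(x)))


class SegmentationNet(nn.Module):
    """Encoder -> (bridge) -> decoder with gated additive skip fusion."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.encoder = ResidualEncoder(config.encoder_depth, config.in_channels, rng)
        if config.use_denseaspp:
            self.bridge = DenseASPP(STAGE_CHANNELS[-1], config.dilation_rates,
                                    config.aspp_reduce, config.aspp_growth, rng)
        if config.use_attention:
            attention = nn.Module()
            attention.skip1 = ChannelAttention(STAGE_CHANNELS[0],
                                               config.attention_reduction, rng)
            attention.skip2 = ChannelAttention(STAGE_CHANNELS[1],
                                               config.attention_reduction, rng)
            attention.skip3 = ChannelAttention(STAGE_CHANNELS[2],
                                               config.attention_reduction, rng)
            self.attention = attention
        self.decoder4 = DecoderBlock(512, 256, rng)
        self.decoder3 = DecoderBlock(256, 128, rng)
        self.decoder2 = DecoderBlock(128, 64, rng)
        self.decoder1 = DecoderBlock(64, 64, rng)
        self.head_up = nn.ConvTranspose2d(64, 32, 3, stride=2, padding=1,
                                          output_padding=1, bias=False, rng=rng)
        self.head_bn = nn.BatchNorm2d(32)
        self.head_conv = nn.Conv2d(32, 32, 3, padding=1, bias=False, rng=rng)
        self.head_conv_bn = nn.BatchNorm2d(32)
        self.head_out = nn.Conv2d(32, config.out_channels, 1, rng=rng)

    # -- staged API ----------------------------------------------------------
    def encode(self, x):
        """Run the encoder; returns ((f1, f2, f3), f4)."""
        x = nn.as_tensor(x)
        if x.ndim != 4:
            raise ShapeError(f"expected a rank-4 (N, C, H, W) input, got rank {x.ndim}")
        _check_input_size(x.shape[2], x.shape[3])
        f1, f2, f3, f4 = self.encoder(x)
        return (f1, f2, f3), f4

    def decode(self, f4, skips):
        """Decode a (possibly bridged) bottleneck with skip fusion."""
        f1, f2, f3 = skips
        if self.config.use_attention:
            f1 = self.attention.skip1(f1)
            f2 = self.attention.skip2(f2)
            f3 = self.attention.skip3(f3)
        for d, f in (("decoder4", f3), ("decoder3", f2), ("decoder2", f1)):
            expected = f.shape
            f4 = getattr(self, d)(f4)
            if f4.shape != expected:
                raise ShapeError(
                    f"skip shape mismatch at {d}: decoder produced {f4.shape}, "
                    f"skip is {expected}")
            f4 = f4 + f
        y = self.decoder1(f4)
        y = F.relu(self.head_bn(self.head_up(y)))
        y = F.relu(self.head_conv_bn(self.head_conv(y)))
        return F.sigmoid(self.head_out(y))

    def forward(self, x):
        skips, f4 = self.encode(x)
        if self.config.use_denseaspp:
            f4 = self.bridge(f4)
        return self.decode(f4, skips)


def build_model(config: ModelConfig | str, seed: int = 0,
                encoder_weights: Optional[str] = None) -> SegmentationNet:
    """Build a variant; optionally warm-start the encoder from an .npz state.

    ``encoder_weights`` is a hook for locally stored encoder state dicts
    (as produced by ``model.encoder.state_dict()`` saved with ``np.savez``);
    by default everything is seeded He-normal initialisation.
    """
    if isinstance(config, str):
        config = build_variant(config)
    model = SegmentationNet(config, seed=seed)
    if encoder_weights is not None:
        with np.load(encoder_weights) as data:
            model.encoder.load_state_dict({k: data[k] for k in data.files})
    return model


def count_params(config: ModelConfig | str) -> int:
    """Number of trainable scalars in the variant described by ``config``."""
    return build_model(config, seed=0).num_parameters()


def parameter_names(config: ModelConfig | str) -> set[str]:
    """Dotted names of all trainable parameters (for subgraph diffs)."""
    return {name for name, _ in build_model(config, seed=0).named_parameters()}
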
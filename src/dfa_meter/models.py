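"""Three-class segmentation networks: DeepLabv3+ (primary), U-Net, PSPNet.

The primary model is a DeepLabv3+ with a MobileNetV2 encoder: a stem
convolution followed by 17 inverted-residual bottlenecks arranged
1 + 2 + 14 — the low-level feature tap sits after the first three
bottlenecks (stride 4), the remaining 14 produce the high-level features at
the configured output stride.  Atrous spatial pyramid pooling (ASPP) runs
parallel dilated 3x3 convolutions, a 1x1 branch and a global-pooling branch
over the high-level features; the decoder upsamples the ASPP output,
concatenates the projected low-level features, refines with two 3x3
convolutions and upsamples to input resolution with one channel per class.

U-Net and PSPNet are canonical minimal baselines for comparison runs.  All
networks accept a ``width_multiplier`` that scales every channel count, so
the same code runs at publication scale and at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F

__all__ = [
    "ModelConfig",
    "build_model",
    "DeepLabV3Plus",
    "MobileNetV2Encoder",
    "InvertedResidual",
    "ASPP",
    "UNet",
    "PSPNet",
]

ARCHITECTURES = ("deeplabv3plus", "unet", "pspnet")

# MobileNetV2 stage plan: (expansion t, channels c, repeats n, stride s).
# Repeats sum to 17 bottlenecks; the low-level tap follows the first 1 + 2.
_MOBILENETV2_STAGES = (
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
)
LOW_LEVEL_TAP = 3  # bottleneck index after which low-level features are taken


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``width_multiplier`` scales all channel widths (1.0 = publication scale,
    0.25 = desk scale); ``atrous_rates`` are the ASPP dilation rates;
    ``output_stride`` is the encoder's output downsampling factor.
    """

    architecture: str = "deeplabv3plus"
    input_size: int = 512
    num_classes: int = 3
    width_multiplier: float = 1.0
    atrous_rates: tuple = (6, 12, 18)
    output_stride: int = 16

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}"
            )
        if self.output_stride not in (8, 16):
            raise ValueError("output_stride must be 8 or 16")
        if self.input_size % self.output_stride != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by output_stride "
                f"{self.output_stride}"
            )
        if self.num_classes != 3:
            raise ValueError("this pipeline segments exactly 3 classes")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")


def _scale(c: int, width_multiplier: float) -> int:
    return max(4, int(round(c * width_multiplier)))


def _conv_bn_act(cin, cout, k, rng, stride=1, padding=0, dilation=1, act="relu6"):
    layers = [
        nn.Conv2d(cin, cout, k, rng, stride, padding, dilation, bias=False),
        nn.BatchNorm2d(cout),
    ]
    if act == "relu6":
        layers.append(nn.ReLU6())
    elif act == "relu":
        layers.append(nn.ReLU())
    return nn.Sequential(*layers)


class InvertedResidual(nn.Module):
    """Expand -> depthwise 3x3 -> project bottleneck with optional residual.

    The residual addition happens exactly when stride is 1 and the input and
    output feature maps have the same shape (same channel count); otherwise
    the block output is the convolution path alone.
    """

    def __init__(self, cin, cout, rng, stride=1, expand_ratio=6, dilation=1):
        super().__init__()
        hidden = cin * expand_ratio
        self.use_residual = stride == 1 and cin == cout
        self.stride, self.expand_ratio, self.dilation = stride, expand_ratio, dilation
        self.in_channels, self.out_channels = cin, cout
        path = []
        if expand_ratio != 1:
            path.append(_conv_bn_act(cin, hidden, 1, rng))
        path.append(
            nn.Sequential(
                nn.DepthwiseConv2d(
                    hidden, 3, rng, stride, padding=dilation, dilation=dilation,
                    bias=False,
                ),
                nn.BatchNorm2d(hidden),
                nn.ReLU6(),
            )
        )
        path.append(
            nn.Sequential(
                nn.Conv2d(hidden, cout, 1, rng, bias=False), nn.BatchNorm2d(cout)
            )
        )
        self.path = nn.Sequential(*path)

    def forward(self, x):
        out = self.path(x)
        if self.use_residual:
            out = F.add(x, out)
        return out


class MobileNetV2Encoder(nn.Module):
    """MobileNetV2 feature extractor with a stride-4 low-level tap.

    ``forward`` returns ``(low_level, high_level)``.  With output stride 16
    the final stride-2 stage runs at stride 1 with doubled dilation instead.
    """

    def __init__(self, rng, width_multiplier=1.0, output_stride=16, in_channels=3):
        super().__init__()
        stem_ch = _scale(32, width_multiplier)
        self.stem = _conv_bn_act(in_channels, stem_ch, 3, rng, stride=2, padding=1)
        self.low_level_index = LOW_LEVEL_TAP
        self.bottlenecks = nn.ModuleList()
        current_stride = 2
        dilation = 1
        cin = stem_ch
        for t, c, n, s in _MOBILENETV2_STAGES:
            cout = _scale(c, width_multiplier)
            for i in range(n):
                stride = s if i == 0 else 1
                if stride == 2 and current_stride >= output_stride:
                    stride = 1
                    dilation *= 2
                elif stride == 2:
                    current_stride *= 2
                self.bottlenecks.append(
                    InvertedResidual(
                        cin, cout, rng, stride, expand_ratio=t, dilation=dilation
                    )
                )
                cin = cout
        self.low_level_channels = self.bottlenecks[LOW_LEVEL_TAP - 1].out_channels
        self.high_level_channels = cin

    def forward(self, x):
        x = self.stem(x)
        low = None
        for i, block in enumerate(self.bottlenecks):
            x = block(x)
            if i + 1 == self.low_level_index:
                low = x
        return low, x


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling over the high-level features."""

    def __init__(self, cin, cout, rng, rates=(6, 12, 18)):
        super().__init__()
        self.branches = nn.ModuleList([_conv_bn_act(cin, cout, 1, rng)])
        for r in rates:
            self.branches.append(
                _conv_bn_act(cin, cout, 3, rng, padding=r, dilation=r)
            )
        self.pool_branch = _conv_bn_act(cin, cout, 1, rng)
        self.project = _conv_bn_act(cout * (len(rates) + 2), cout, 1, rng)

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        outs = [b(x) for b in self.branches]
        pooled = F.adaptive_avg_pool2d(x, 1, 1)
        pooled = self.pool_branch(pooled)
        outs.append(F.resize_bilinear(pooled, h, w))
        return self.project(F.concat(outs, axis=1))


class DeepLabV3Plus(nn.Module):
    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        wm = config.width_multiplier
        self.config = config
        self.encoder = MobileNetV2Encoder(
            rng, width_multiplier=wm, output_stride=config.output_stride
        )
        aspp_ch = _scale(256, wm)
        self.aspp = ASPP(
            self.encoder.high_level_channels, aspp_ch, rng, config.atrous_rates
        )
        self.low_level_project = _conv_bn_act(
            self.encoder.low_level_channels, _scale(48, wm), 1, rng
        )
        dec_ch = _scale(256, wm)
        self.decoder = nn.Sequential(
            _conv_bn_act(aspp_ch + _scale(48, wm), dec_ch, 3, rng, padding=1),
            _conv_bn_act(dec_ch, dec_ch, 3, rng, padding=1),
        )
        self.classifier = nn.Conv2d(dec_ch, config.num_classes, 1, rng)

    def forward(self, x):
        in_h, in_w = x.shape[2], x.shape[3]
        low, high = self.encoder(x)
        out = self.aspp(high)
        out = F.resize_bilinear(out, low.shape[2], low.shape[3])
        out = F.concat([out, self.low_level_project(low)], axis=1)
        out = self.decoder(out)
        out = self.classifier(out)
        return F.resize_bilinear(out, in_h, in_w)


class _DoubleConv(nn.Module):
    def __init__(self, cin, cout, rng):
        super().__init__()
        self.block = nn.Sequential(
            _conv_bn_act(cin, cout, 3, rng, padding=1, act="relu"),
            _conv_bn_act(cout, cout, 3, rng, padding=1, act="relu"),
        )

    def forward(self, x):
        return self.block(x)


class UNet(nn.Module):
    """Canonical 4-down/4-up U-Net with bilinear upsampling."""

    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        self.config = config
        base = _scale(64, config.width_multiplier)
        chans = [base, base * 2, base * 4, base * 8, base * 16]
        self.downs = nn.ModuleList()
        cin = 3
        for c in chans[:-1]:
            self.downs.append(_DoubleConv(cin, c, rng))
            cin = c
        self.bottom = _DoubleConv(chans[-2], chans[-1], rng)
        self.ups = nn.ModuleList()
        for skip_c, up_c in zip(reversed(chans[:-1]), reversed(chans[1:])):
            self.ups.append(_DoubleConv(up_c + skip_c, skip_c, rng))
        self.classifier = nn.Conv2d(chans[0], config.num_classes, 1, rng)

    def forward(self, x):
        skips = []
        for down in self.downs:
            x = down(x)
            skips.append(x)
            x = F.max_pool2d(x)
        x = self.bottom(x)
        for up, skip in zip(self.ups, reversed(skips)):
            x = F.resize_bilinear(x, skip.shape[2], skip.shape[3])
            x = up(F.concat([x, skip], axis=1))
        return self.classifier(x)


class PSPNet(nn.Module):
    """Pyramid scene parsing on a reduced stride-8 convolutional backbone."""

    BINS = (1, 2, 3, 6)

    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        self.config = config
        wm = config.width_multiplier
        c1, c2, c3 = _scale(64, wm), _scale(128, wm), _scale(256, wm)
        self.backbone = nn.Sequential(
            _conv_bn_act(3, c1, 3, rng, stride=2, padding=1, act="relu"),
            _conv_bn_act(c1, c2, 3, rng, stride=2, padding=1, act="relu"),
            _conv_bn_act(c2, c3, 3, rng, stride=2, padding=1, act="relu"),
            _conv_bn_act(c3, c3, 3, rng, padding=1, act="relu"),
        )
        branch_ch = max(4, c3 // len(self.BINS))
        self.pyramid = nn.ModuleList(
            [_conv_bn_act(c3, branch_ch, 1, rng, act="relu") for _ in self.BINS]
        )
        self.head = nn.Sequential(
            _conv_bn_act(
                c3 + branch_ch * len(self.BINS), c2, 3, rng, padding=1, act="relu"
            ),
            nn.Conv2d(c2, config.num_classes, 1, rng),
        )

    def forward(self, x):
        in_h, in_w = x.shape[2], x.shape[3]
        feat = self.backbone(x)
        h, w = feat.shape[2], feat.shape[3]
        outs = [feat]
        for bins, branch in zip(self.BINS, self.pyramid):
            pooled = F.adaptive_avg_pool2d(feat, bins, bins)
            outs.append(F.resize_bilinear(branch(pooled), h, w))
        out = self.head(F.concat(outs, axis=1))
        return F.resize_bilinear(out, in_h, in_w)


def build_model(config: ModelConfig, seed: int = 0) -> nn.Module:
    """Instantiate the configured architecture with seeded initialization."""
    rng = np.random.default_rng(seed)
    if config.architecture == "deeplabv3plus":
        return DeepLabV3Plus(config, rng)
    if config.architecture == "unet":
        return UNet(config, rng)
    return PSPNet(config, rng)
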
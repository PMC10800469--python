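"""Stage-1 leaf segmentation network (L-DPNet).

A pyramid-scene-parsing segmenter pruned for the two-class leaf/background
task: a ResNet-style backbone at output stride 8, a pyramid pooling module
reduced to the 1x1 and 6x6 bins, and a DP module — a deformable 3x3
convolution attached to the 6x6 branch whose output is added element-wise
back onto that branch. Each pooling branch halves the backbone channels with
a 1x1 convolution and is bilinearly upsampled to the feature-map size; the
input map and all branches are concatenated and fused by a 3x3 convolution
before the 2-class head. Logits are bilinearly upsampled to the input
resolution (non-corner-aligned convention throughout).

The deformable convolution's offset predictor is zero-initialized, so a
fresh model is exactly the deformable-free pruned variant at step 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import autograd as F

__all__ = ["PPMConfig", "DPModuleConfig", "BackboneConfig", "LDPNetConfig",
           "PyramidPooling", "LDPNet"]


@dataclass(frozen=True)
class PPMConfig:
    bins: tuple = (1, 6)
    branch_channel_divisor: int = 2
    upsample_mode: str = "bilinear"

    def __post_init__(self):
        if not self.bins or any(b < 1 for b in self.bins):
            raise ValueError("bins must be non-empty positive grid sizes")


@dataclass(frozen=True)
class DPModuleConfig:
    attach_to: tuple = (6,)   # bins that receive a deformable 3x3 convolution

    def validate(self, bins):
        extra = set(self.attach_to) - set(bins)
        if extra:
            raise ValueError(f"DP module attached to absent bin(s) {sorted(extra)}")


@dataclass(frozen=True)
class BackboneConfig:
    """ResNet-bottleneck feature extractor at output stride 8.

    Defaults mirror ResNet-50 (depths 3,4,6,3, expansion 4); the tiny preset
    is a thin trainable-on-CPU variant for tests and synthetic data.
    """

    stem_width: int = 64
    stage_widths: tuple = (64, 128, 256, 512)
    depths: tuple = (3, 4, 6, 3)
    expansion: int = 4

    @property
    def out_channels(self) -> int:
        return self.stage_widths[-1] * self.expansion

    @classmethod
    def tiny(cls) -> "BackboneConfig":
        return cls(stem_width=16, stage_widths=(8, 12, 16, 16),
                   depths=(1, 1, 1, 1), expansion=2)


@dataclass(frozen=True)
class LDPNetConfig:
    input_size: tuple = (473, 473)
    num_classes: int = 2
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    ppm: PPMConfig = field(default_factory=PPMConfig)
    dp: DPModuleConfig = field(default_factory=DPModuleConfig)

    def __post_init__(self):
        if self.num_classes != 2:
            raise ValueError("leaf segmentation is two-class")
        self.dp.validate(self.ppm.bins)

    @classmethod
    def tiny(cls, input_size=(64, 64), bins=(1, 6), attach_to=(6,)) -> "LDPNetConfig":
        return cls(input_size=input_size, backbone=BackboneConfig.tiny(),
                   ppm=PPMConfig(bins=tuple(bins)),
                   dp=DPModuleConfig(attach_to=tuple(attach_to)))


class Bottleneck(nn.Module):
    def __init__(self, cin, width, cout, stride=1, dilation=1, rng=None):
        super().__init__()
        self.reduce = nn.ConvBNReLU(cin, width, 1, rng=rng)
        self.conv = nn.ConvBNReLU(width, width, 3, stride=stride, dilation=dilation,
                                  rng=rng)
        self.expand_conv = nn.Conv2d(width, cout, 1, bias=False, rng=rng)
        self.expand_bn = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.proj_conv = nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng)
            self.proj_bn = nn.BatchNorm2d(cout)
        else:
            self.proj_conv = None
        self.act = nn.ReLU()

    def forward(self, x):
        y = self.expand_bn(self.expand_conv(self.conv(self.reduce(x))))
        skip = self.proj_bn(self.proj_conv(x)) if self.proj_conv is not None else x
        return self.act(F.add(y, skip))


class Backbone(nn.Module):
    """Stem (stride 4) + four bottleneck stages; stages 3-4 dilated, stride 8."""

    def __init__(self, cfg: BackboneConfig, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.stem = nn.ConvBNReLU(3, cfg.stem_width, 3, stride=2, rng=rng)
        self.pool = nn.MaxPool2d(2)
        stages = []
        cin = cfg.stem_width
        plan = [  # (stride, dilation) per stage
            (1, 1), (2, 1), (1, 2), (1, 4),
        ]
        for width, depth, (stride, dil) in zip(cfg.stage_widths, cfg.depths, plan):
            cout = width * cfg.expansion
            blocks = [Bottleneck(cin, width, cout, stride=stride, dilation=dil,
                                 rng=rng)]
            blocks += [Bottleneck(cout, width, cout, dilation=dil, rng=rng)
                       for _ in range(depth - 1)]
            stages.append(nn.Sequential(*blocks))
            cin = cout
        self.stages = stages

    def forward(self, x):
        x = self.pool(self.stem(x))
        for stage in self.stages:
            x = stage(x)
        return x


class PyramidPooling(nn.Module):
    """Pruned pyramid pooling with optional DP (deformable) branch modules."""

    def __init__(self, cin, ppm: PPMConfig, dp: DPModuleConfig, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.bins = tuple(ppm.bins)
        cb = cin // ppm.branch_channel_divisor
        if cb * ppm.branch_channel_divisor != cin:
            raise ValueError(
                f"divisor {ppm.branch_channel_divisor} does not divide {cin} channels")
        self.branch_convs = [nn.ConvBNReLU(cin, cb, 1, rng=rng) for _ in self.bins]
        self.dp_bins = tuple(dp.attach_to)
        self.dp_convs = [nn.DeformConv2d(cb, cb, 3, rng=rng) for _ in self.dp_bins]
        concat_c = cin + cb * len(self.bins)
        self.fuse = nn.ConvBNReLU(concat_c, cb, 3, rng=rng)
        self.last_concat_channels = None

    def forward(self, x):
        n, c, h, w = x.data.shape
        if max(self.bins) > min(h, w):
            raise ValueError(
                f"pooling bin {max(self.bins)} exceeds feature map size {(h, w)}")
        feats = [x]
        for b, conv in zip(self.bins, self.branch_convs):
            branch = conv(F.adaptive_avg_pool2d(x, (b, b)))
            branch = F.upsample_bilinear(branch, (h, w))
            if b in self.dp_bins:
                dp = self.dp_convs[self.dp_bins.index(b)]
                branch = F.add(dp(branch), branch)
            feats.append(branch)
        cat = F.concat(feats, axis=1)
        self.last_concat_channels = cat.data.shape[1]
        return self.fuse(cat)


class LDPNet(nn.Module):
    def __init__(self, cfg: LDPNetConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg if cfg is not None else LDPNetConfig()
        rng = np.random.default_rng(seed)
        self.backbone = Backbone(self.cfg.backbone, rng=rng)
        cin = self.cfg.backbone.out_channels
        self.ppm = PyramidPooling(cin, self.cfg.ppm, self.cfg.dp, rng=rng)
        cb = cin // self.cfg.ppm.branch_channel_divisor
        self.head = nn.Conv2d(cb, self.cfg.num_classes, 1, rng=rng)

    def forward(self, x):
        """Per-pixel 2-class logits at the input resolution; x is (N,3,H,W)."""
        if isinstance(x, np.ndarray):
            x = nn.Tensor(x)
        if x.data.ndim != 4 or x.data.shape[1] != 3:
            raise ValueError(f"expected (N,3,H,W) input, got {x.data.shape}")
        h, w = x.data.shape[2:]
        feats = self.backbone(x)
        fused = self.ppm(feats)
        logits = self.head(fused)
        return F.upsample_bilinear(logits, (h, w))

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Argmax leaf mask for one HxWx3 image in [0,255]."""
        x = (np.asarray(image, np.float32) / 127.5 - 1.0).transpose(2, 0, 1)[None]
        self.eval()
        with F.no_grad():
            logits = self.forward(nn.Tensor(x))
        return logits.data[0].argmax(axis=0).astype(np.uint8)
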
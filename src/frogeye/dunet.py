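"""Stage-2 lesion segmentation network (D-UNet) and the focal loss.

The encoder is the 13-convolution / 4-max-pool front of a VGG16-style
network (the 5th pool and all fully connected layers dropped), with a batch
normalization layer inserted before each ReLU. It emits five feature levels
at strides 1, 2, 4, 8 and 16. The decoder upsamples x2 per stage — bilinear
interpolation by default, transposed convolution as the ablation variant —
concatenates the matching encoder skip, and applies two convolutions with
BN+ReLU, ending in a stride-1 two-class head.

Training minimizes the focal loss

    FL(p_t) = -(1 - p_t)^gamma * log(p_t),   gamma = 2 by default,

where p_t is the softmax probability of the pixel's true class; the
modulating factor down-weights easy pixels to counter the heavy class
imbalance between lesion and healthy tissue. No class-balancing alpha
weight is applied. Probabilities are clamped at 1e-8 before the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import autograd as F

logger = logging.getLogger(__name__)

__all__ = ["EncoderConfig", "DecoderConfig", "FocalLossConfig", "DUNetConfig",
           "DUNet", "focal_loss"]


@dataclass(frozen=True)
class EncoderConfig:
    conv_blocks: tuple = (2, 2, 3, 3, 3)
    channels: tuple = (64, 128, 256, 512, 512)
    bn_before_relu: bool = True

    def __post_init__(self):
        if sum(self.conv_blocks) != 13 and self.channels == (64, 128, 256, 512, 512):
            raise ValueError("full-width encoder must total 13 convolutions")

    @classmethod
    def tiny(cls, bn: bool = True) -> "EncoderConfig":
        return cls(conv_blocks=(1, 1, 2, 2, 2), channels=(8, 12, 16, 24, 24),
                   bn_before_relu=bn)


@dataclass(frozen=True)
class DecoderConfig:
    upsample_mode: str = "bilinear"   # or "transposed"

    def __post_init__(self):
        if self.upsample_mode not in ("bilinear", "transposed"):
            raise ValueError(f"unknown upsample mode {self.upsample_mode!r}")


@dataclass(frozen=True)
class FocalLossConfig:
    gamma: float = 2.0
    reduction: str = "mean"
    eps: float = 1e-8

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass(frozen=True)
class DUNetConfig:
    input_size: tuple = (512, 512)
    num_classes: int = 2
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    loss: FocalLossConfig = field(default_factory=FocalLossConfig)

    @classmethod
    def tiny(cls, input_size=(64, 64), bn=True, mode="bilinear") -> "DUNetConfig":
        return cls(input_size=input_size, encoder=EncoderConfig.tiny(bn),
                   decoder=DecoderConfig(upsample_mode=mode))

    @classmethod
    def from_ablation_flags(cls, normalized_layer: bool,
                            bilinear_interpolation: bool,
                            tiny: bool = False, input_size=None) -> "DUNetConfig":
        """Construct a variant by the ablation-table switches: batch
        normalization on/off and bilinear vs transposed upsampling."""
        mode = "bilinear" if bilinear_interpolation else "transposed"
        if tiny:
            return cls.tiny(input_size or (64, 64), bn=normalized_layer,
                            mode=mode)
        return cls(input_size=input_size or (512, 512),
                   encoder=EncoderConfig(bn_before_relu=normalized_layer),
                   decoder=DecoderConfig(upsample_mode=mode))


class _ConvAct(nn.Module):
    """3x3 convolution + (optional BN) + ReLU."""

    def __init__(self, cin, cout, bn, rng):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 3, bias=not bn, rng=rng)
        self.bn = nn.BatchNorm2d(cout) if bn else None
        self.act = nn.ReLU()

    def forward(self, x):
        x = self.conv(x)
        if self.bn is not None:
            x = self.bn(x)
        return self.act(x)


class DUNet(nn.Module):
    def __init__(self, cfg: DUNetConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg if cfg is not None else DUNetConfig()
        enc, dec = self.cfg.encoder, self.cfg.decoder
        rng = np.random.default_rng(seed)
        bn = enc.bn_before_relu
        self.enc_blocks = []
        cin = 3
        for n_conv, cout in zip(enc.conv_blocks, enc.channels):
            layers = []
            for _ in range(n_conv):
                layers.append(_ConvAct(cin, cout, bn, rng))
                cin = cout
            self.enc_blocks.append(nn.Sequential(*layers))
        self.pools = [nn.MaxPool2d(2) for _ in range(4)]
        self.up_convs = []       # transposed-mode upsamplers (unused for bilinear)
        self.dec_blocks = []
        c_top = enc.channels[4]
        c_prev = c_top
        for skip_c in reversed(enc.channels[:4]):
            if dec.upsample_mode == "transposed":
                self.up_convs.append(nn.ConvTranspose2d(c_prev, c_prev, 2, rng=rng))
            block = nn.Sequential(_ConvAct(c_prev + skip_c, skip_c, bn, rng),
                                  _ConvAct(skip_c, skip_c, bn, rng))
            self.dec_blocks.append(block)
            c_prev = skip_c
        self.head = nn.Conv2d(c_prev, self.cfg.num_classes, 1, rng=rng)

    def forward(self, x):
        """Two-class logits at input resolution; input must be /16-divisible."""
        if isinstance(x, np.ndarray):
            x = nn.Tensor(x)
        if x.data.ndim != 4 or x.data.shape[1] != 3:
            raise ValueError(f"expected (N,3,H,W) input, got {x.data.shape}")
        h, w = x.data.shape[2:]
        if h % 16 or w % 16:
            need = ((-h) % 16, (-w) % 16)
            raise ValueError(
                f"input {h}x{w} not divisible by 16; pad by {need[0]} rows and "
                f"{need[1]} cols")
        skips = []
        for i, block in enumerate(self.enc_blocks):
            x = block(x)
            skips.append(x)
            if i < 4:
                x = self.pools[i](x)
        x = skips[-1]
        for i, (skip, block) in enumerate(zip(reversed(skips[:4]), self.dec_blocks)):
            if self.cfg.decoder.upsample_mode == "transposed":
                x = self.up_convs[i](x)
            else:
                x = F.upsample_bilinear(x, skip.data.shape[2:])
            x = block(F.concat([x, skip], axis=1))
        return self.head(x)

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Argmax lesion mask for one HxWx3 image in [0,255]."""
        x = (np.asarray(image, np.float32) / 127.5 - 1.0).transpose(2, 0, 1)[None]
        self.eval()
        with F.no_grad():
            logits = self.forward(nn.Tensor(x))
        return logits.data[0].argmax(axis=0).astype(np.uint8)


def focal_loss(p: np.ndarray, t: np.ndarray, cfg: FocalLossConfig | None = None
               ) -> float:
    """Focal loss from predicted class probabilities and an integer target mask.

    ``p`` has class probabilities on its last axis; ``t`` holds the true class
    index per pixel. p_t is the probability assigned to the true class;
    gamma=0 reduces to mean cross-entropy. Zero probabilities are clamped at
    ``cfg.eps`` (logged) rather than producing infinities.
    """
    cfg = cfg if cfg is not None else FocalLossConfig()
    p = np.asarray(p, dtype=np.float64)
    t = np.asarray(t, dtype=np.int64)
    if p.shape[:-1] != t.shape:
        raise ValueError(f"probability shape {p.shape} does not match target "
                         f"{t.shape}")
    pt = np.take_along_axis(p, t[..., None], axis=-1)[..., 0]
    if (pt <= 0).any():
        logger.warning("focal loss: %d pixel(s) with p_t <= 0 clamped to %g",
                       int((pt <= 0).sum()), cfg.eps)
    pt = np.clip(pt, cfg.eps, 1.0)
    per_pixel = -((1.0 - pt) ** cfg.gamma) * np.log(pt)
    if cfg.reduction == "mean":
        return float(per_pixel.mean())
    if cfg.reduction == "sum":
        return float(per_pixel.sum())
    raise ValueError(f"unknown reduction {cfg.reduction!r}")
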
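"""Residual U-Net spatial branch.

Encoder: an E0 stem (7x7 stride-2 convolution + BN + ReLU followed by 3x3
stride-2 max pooling) and four stages of bottleneck residual blocks with
the 50-layer topology (3, 4, 6, 3 blocks).  Inter-stage downsampling is
carried by the stride-2 3x3 convolution inside the first bottleneck of
each stage — no pooling beyond the stem.  Each block computes
``y = ReLU(F(x) + shortcut(x))`` with F = 1x1 conv-BN-ReLU -> 3x3
conv-BN-ReLU (stride here) -> 1x1 conv-BN; the shortcut is the identity or
a 1x1 projection whenever the shape changes.

The feature pyramid is captured after the stem convolution (scale /2) and
after each stage (/4, /8, /16, /32), which gives the decoder exactly one
skip per upsampling module.

Decoder: four symmetric modules of {transposed conv (k=2, s=2) ->
concatenate skip -> 3x3 conv + ReLU}, then a D0 module (transposed conv +
3x3 conv) restoring the input resolution with a single logit channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor


@dataclass(frozen=True)
class ResidualBlockSpec:
    in_channels: int
    mid_channels: int
    out_channels: int
    stride: int = 1

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError("bottleneck stride must be 1 or 2")

    @property
    def needs_projection(self) -> bool:
        return self.stride == 2 or self.in_channels != self.out_channels


class Bottleneck(nn.Module):
    def __init__(self, spec: ResidualBlockSpec, rng=None, dtype=np.float32):
        super().__init__()
        self.spec = spec
        self.conv1 = nn.Conv2d(spec.in_channels, spec.mid_channels, 1, bias=False,
                               rng=rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(spec.mid_channels, dtype=dtype)
        self.conv2 = nn.Conv2d(spec.mid_channels, spec.mid_channels, 3,
                               stride=spec.stride, bias=False, rng=rng, dtype=dtype)
        self.bn2 = nn.BatchNorm2d(spec.mid_channels, dtype=dtype)
        self.conv3 = nn.Conv2d(spec.mid_channels, spec.out_channels, 1, bias=False,
                               rng=rng, dtype=dtype)
        self.bn3 = nn.BatchNorm2d(spec.out_channels, dtype=dtype)
        if spec.needs_projection:
            self.proj = nn.Conv2d(spec.in_channels, spec.out_channels, 1,
                                  stride=spec.stride, bias=False, rng=rng, dtype=dtype)
            self.proj_bn = nn.BatchNorm2d(spec.out_channels, dtype=dtype)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.spec.in_channels:
            raise ValueError("bottleneck: channel mismatch")
        y = F.relu(self.bn1(self.conv1(x)))
        y = F.relu(self.bn2(self.conv2(y)))
        y = self.bn3(self.conv3(y))
        s = self.proj_bn(self.proj(x)) if self.proj is not None else x
        return F.relu(F.add(y, s))

    def macs(self, hw):
        total, hw1 = self.conv1.macs(hw)
        m, hw2 = self.conv2.macs(hw1)
        total += m
        total += self.conv3.macs(hw2)[0]
        if self.proj is not None:
            total += self.proj.macs(hw)[0]
        return total, hw2


@dataclass
class EncoderPyramid:
    """Per-scale feature maps: e0 at /2 (post-stem conv), e1../4, e2../8,
    e3../16, e4../32."""
    e0: Tensor
    e1: Tensor
    e2: Tensor
    e3: Tensor
    e4: Tensor

    def skips(self):
        """Skip features paired with their downsample factors, deepest first
        (the decoder consumes them in this order)."""
        return [(16, self.e3), (8, self.e2), (4, self.e1), (2, self.e0)]


STAGE_BLOCKS = (3, 4, 6, 3)


class Encoder(nn.Module):
    def __init__(self, stem_width: int, stage_mids, stage_outs,
                 in_channels: int = 1, rng=None, dtype=np.float32):
        super().__init__()
        self.stem = nn.Conv2d(in_channels, stem_width, 7, stride=2, padding=3,
                              bias=False, rng=rng, dtype=dtype)
        self.stem_bn = nn.BatchNorm2d(stem_width, dtype=dtype)
        self.pool = nn.MaxPool2d(3, 2, 1)
        self.stages = []
        cin = stem_width
        for si, (mid, out, nblocks) in enumerate(zip(stage_mids, stage_outs, STAGE_BLOCKS)):
            blocks = []
            for b in range(nblocks):
                stride = 2 if (b == 0 and si > 0) else 1
                blocks.append(Bottleneck(
                    ResidualBlockSpec(cin, mid, out, stride), rng=rng, dtype=dtype))
                cin = out
            self.stages.append(nn.Sequential(*blocks))
        self.widths = (stem_width, *stage_outs)

    def forward(self, x: Tensor) -> EncoderPyramid:
        size = x.shape[2]
        if size % 32 or x.shape[3] % 32 or x.shape[2] != x.shape[3]:
            raise ValueError("encoder input must be square with size divisible by 32")
        e0 = F.relu(self.stem_bn(self.stem(x)))
        y = self.pool(e0)
        feats = []
        for stage in self.stages:
            y = stage(y)
            feats.append(y)
        return EncoderPyramid(e0, *feats)

    def macs(self, hw):
        total, hw = self.stem.macs(hw)
        _, hw = self.pool.macs(hw)
        for stage in self.stages:
            m, hw = stage.macs(hw)
            total += m
        return total, hw


class Decoder(nn.Module):
    """Four upsampling modules + D0.  ``skip_widths`` are the channel counts
    of the incoming (possibly fused) skips, deepest first."""

    def __init__(self, bottom_width: int, up_widths, skip_widths, d0_width: int,
                 rng=None, dtype=np.float32):
        super().__init__()
        if len(up_widths) != 4 or len(skip_widths) != 4:
            raise ValueError("decoder expects four upsampling modules")
        self.ups = []
        self.convs = []
        cin = bottom_width
        for d, s in zip(up_widths, skip_widths):
            self.ups.append(nn.ConvTranspose2d(cin, d, 2, 2, bias=True,
                                               rng=rng, dtype=dtype))
            self.convs.append(nn.Conv2d(d + s, d, 3, bias=True, rng=rng, dtype=dtype))
            cin = d
        self.d0_up = nn.ConvTranspose2d(cin, d0_width, 2, 2, bias=True,
                                        rng=rng, dtype=dtype)
        self.d0_conv = nn.Conv2d(d0_width, 1, 3, bias=True, rng=rng, dtype=dtype)
        self.skip_widths = tuple(skip_widths)

    def forward(self, bottom: Tensor, fused_skips) -> Tensor:
        """``fused_skips``: deepest-first list matching the four modules."""
        y = bottom
        for up, conv, skip in zip(self.ups, self.convs, fused_skips):
            y = up(y)
            if y.shape[2:] != skip.shape[2:]:
                raise ValueError("decoder: skip spatial size mismatch")
            if skip.shape[1] != conv.cin - up.cout:
                raise ValueError("decoder: skip channel mismatch")
            y = F.relu(conv(F.concat([y, skip], axis=1)))
        y = F.relu(self.d0_up(y))
        return self.d0_conv(y)          # logits, (N, 1, H, W)

    def macs(self, hw):
        total = 0
        for up, conv in zip(self.ups, self.convs):
            m, hw = up.macs(hw)
            total += m
            total += conv.macs(hw)[0]
        m, hw = self.d0_up.macs(hw)
        total += m
        total += self.d0_conv.macs(hw)[0]
        return total, hw


def residual_block(x, spec: ResidualBlockSpec, block: Bottleneck | None = None,
                   rng=None):
    """Functional wrapper: apply (or build then apply) one bottleneck block."""
    if block is None:
        block = Bottleneck(spec, rng=rng)
    x = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    return block(x)
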
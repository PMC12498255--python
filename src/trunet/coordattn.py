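"""Coordinate attention.

Features are pooled independently along the height and width axes,

    z_h[c, i] = mean_j X[c, i, j],      z_w[c, j] = mean_i X[c, i, j],

the two descriptors are concatenated along the pooled spatial axis and
passed through a shared 1x1 convolution F1 with ReLU, split back at index
H, and mapped by per-axis 1x1 convolutions Fh, Fw with sigmoid into
factorised gates.  The input is recalibrated as

    Y[c, i, j] = X[c, i, j] * g_h[c, i] * g_w[c, j].

The shared transform uses ReLU (not hard-swish) and carries no batch
normalisation.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor


class CoordinateAttention(nn.Module):
    def __init__(self, channels: int, reduction: int = 16, rng=None, dtype=np.float32):
        super().__init__()
        if reduction < 1:
            raise ValueError("reduction ratio must be a positive integer")
        mid = max(8, channels // reduction)
        self.channels = channels
        self.mid = mid
        self.f1 = nn.Conv2d(channels, mid, 1, bias=True, rng=rng, dtype=dtype)
        self.fh = nn.Conv2d(mid, channels, 1, bias=True, rng=rng, dtype=dtype)
        self.fw = nn.Conv2d(mid, channels, 1, bias=True, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if h == 0 or w == 0:
            raise ValueError("coordinate attention needs non-empty spatial axes")
        z_h = F.mean(x, axis=3, keepdims=True)              # (N, C, H, 1)
        z_w = F.reshape(F.mean(x, axis=2, keepdims=True), (n, c, w, 1))
        z = F.concat([z_h, z_w], axis=2)                    # (N, C, H+W, 1)
        f = F.relu(self.f1(z))
        f_h = F.narrow(f, 2, 0, h)
        f_w = F.narrow(f, 2, h, w)
        g_h = F.sigmoid(self.fh(f_h))                       # (N, C, H, 1)
        g_w = F.reshape(F.sigmoid(self.fw(f_w)), (n, c, 1, w))
        return F.mul(F.mul(x, g_h), g_w)

    def macs(self, hw) -> int:
        h, w = hw
        return (self.channels * self.mid * (h + w)
                + self.mid * self.channels * h
                + self.mid * self.channels * w)


def coord_attention(x, module: CoordinateAttention):
    x = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    return module(x)
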
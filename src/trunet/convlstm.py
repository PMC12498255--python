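"""Convolutional LSTM temporal feature extraction.

The cell follows the peephole formulation in which the input-to-state and
state-to-state transitions are same-padding convolutions and the peephole
terms act by per-channel Hadamard products:

    f_t = sigma(Wxf*x_t + Whf*h_{t-1} + Wcf . c_{t-1} + b_f)
    i_t = sigma(Wxi*x_t + Whi*h_{t-1} + Wci . c_{t-1} + b_i)
    g_t = tanh (Wxc*x_t + Whc*h_{t-1} + b_c)
    c_t = f_t . c_{t-1} + i_t . g_t
    o_t = sigma(Wxo*x_t + Who*h_{t-1} + Wco . c_t + b_o)
    h_t = o_t . tanh(c_t)

Note the output gate peeps at the *new* cell state c_t.  Peephole weights
are per-channel scalars broadcast over space, which keeps the cell
agnostic to input size.  Memory is zero-initialised at the start of every
sequence.

The temporal branch wraps a stack of cells between an E0-like stem and a
small feature head.  Calibration against the printed complexity budgets of
the full-scale model pins the branch to a coarse fixed grid (8x8 at the
reference 512-pixel input): the stem's stride-4 convolution is followed by
parameter-free average pooling down to the grid, and the per-scale outputs
are channel-matched by 1x1 convolutions and resized (nearest neighbour,
parameter-free) to each skip resolution.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor


class CellState:
    """Paired hidden/cell feature maps carried across ConvLSTM steps."""

    __slots__ = ("h", "c")

    def __init__(self, h: Tensor, c: Tensor):
        if h.shape != c.shape:
            raise ValueError("CellState: h and c must share shape")
        self.h = h
        self.c = c

    @classmethod
    def zeros(cls, n: int, channels: int, hw, dtype=np.float32) -> "CellState":
        shape = (n, channels, hw[0], hw[1])
        return cls(Tensor(np.zeros(shape, dtype=dtype)),
                   Tensor(np.zeros(shape, dtype=dtype)))


class ConvLSTMCell(nn.Module):
    def __init__(self, in_channels: int, hidden_channels: int, kernel: int = 3,
                 rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.hidden_channels = hidden_channels
        self.kernel = kernel
        conv = lambda cin: nn.Conv2d(cin, hidden_channels, kernel, bias=False,
                                     rng=rng, dtype=dtype)
        # input-path and state-path kernels for each gate
        self.wxf, self.whf = conv(in_channels), conv(hidden_channels)
        self.wxi, self.whi = conv(in_channels), conv(hidden_channels)
        self.wxc, self.whc = conv(in_channels), conv(hidden_channels)
        self.wxo, self.who = conv(in_channels), conv(hidden_channels)
        # per-channel peephole weights and gate biases
        zeros = lambda: Tensor(np.zeros(hidden_channels, dtype=dtype), requires_grad=True)
        self.wcf, self.wci, self.wco = zeros(), zeros(), zeros()
        self.bf, self.bi, self.bc, self.bo = zeros(), zeros(), zeros(), zeros()

    def _peep(self, w: Tensor, c: Tensor) -> Tensor:
        return F.mul(F.reshape(w, (1, self.hidden_channels, 1, 1)), c)

    def _bias(self, b: Tensor) -> Tensor:
        return F.reshape(b, (1, self.hidden_channels, 1, 1))

    def forward(self, x: Tensor, state: CellState):
        if x.shape[2:] != state.h.shape[2:]:
            raise ValueError("ConvLSTM step: spatial size of input and state differ")
        h, c = state.h, state.c
        f = F.sigmoid(F.add(F.add(F.add(self.wxf(x), self.whf(h)),
                                  self._peep(self.wcf, c)), self._bias(self.bf)))
        i = F.sigmoid(F.add(F.add(F.add(self.wxi(x), self.whi(h)),
                                  self._peep(self.wci, c)), self._bias(self.bi)))
        g = F.tanh(F.add(F.add(self.wxc(x), self.whc(h)), self._bias(self.bc)))
        c_new = F.add(F.mul(f, c), F.mul(i, g))
        o = F.sigmoid(F.add(F.add(F.add(self.wxo(x), self.who(h)),
                                  self._peep(self.wco, c_new)), self._bias(self.bo)))
        h_new = F.mul(o, F.tanh(c_new))
        return h_new, CellState(h_new, c_new)

    def step_macs(self, hw) -> int:
        per_conv_x = self.wxf.macs(hw)[0]
        per_conv_h = self.whf.macs(hw)[0]
        return 4 * per_conv_x + 4 * per_conv_h


def convlstm_step(x, state: CellState, cell: ConvLSTMCell):
    """Single-step functional form (wraps :meth:`ConvLSTMCell.forward`)."""
    x = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    return cell(x, state)


class ConvLSTMStack(nn.Module):
    """Cascaded ConvLSTM layers; layer l consumes layer l-1's hidden outputs."""

    def __init__(self, in_channels: int, hidden_channels: int, layers: int = 2,
                 kernel: int = 3, rng=None, dtype=np.float32):
        super().__init__()
        if layers < 1:
            raise ValueError("need at least one ConvLSTM layer")
        self.cells = []
        cin = in_channels
        for _ in range(layers):
            self.cells.append(ConvLSTMCell(cin, hidden_channels, kernel, rng, dtype))
            cin = hidden_channels
        self.hidden_channels = hidden_channels
        self.dtype = dtype

    def run_sequence(self, xs) -> Tensor:
        """Process slices oldest->newest from zero state; return the top
        layer's hidden state after the final (target) step."""
        xs = [x if isinstance(x, Tensor) else Tensor(np.asarray(x)) for x in xs]
        if not xs:
            raise ValueError("empty sequence")
        n, _, h, w = xs[0].shape
        states = [CellState.zeros(n, c.hidden_channels, (h, w), dtype=self.dtype)
                  for c in self.cells]
        top = None
        current = xs
        for li, cell in enumerate(self.cells):
            outs = []
            state = states[li]
            for x in current:
                out, state = cell(x, state)
                outs.append(out)
            current = outs
            top = outs[-1]
        return top

    forward = run_sequence

    def seq_macs(self, hw, T: int) -> int:
        return T * sum(c.step_macs(hw) for c in self.cells)


def run_sequence(unit_slices, stack: ConvLSTMStack) -> Tensor:
    return stack.run_sequence(unit_slices)


def temporal_pyramid(h_final: Tensor, branch: "TemporalBranch",
                     image_size: int) -> dict:
    """Resolution adjustment of a final hidden state: feature head, per-scale
    channel matching and parameter-free resizing to each skip resolution."""
    h = h_final if isinstance(h_final, Tensor) else Tensor(np.asarray(h_final))
    for i in range(0, len(branch.head), 2):
        h = F.relu(branch.head[i + 1](branch.head[i](h)))
    return {f: _resize_to(conv(h), image_size // f)
            for f, conv in zip(branch.skip_factors, branch.match)}


def _resize_to(x: Tensor, target: int) -> Tensor:
    """Parameter-free resize from the branch grid to a skip resolution."""
    size = x.shape[2]
    if target == size:
        return x
    if target > size:
        if target % size:
            raise ValueError(f"cannot reach {target} from {size} by integer scaling")
        return F.upsample_nearest(x, target // size)
    if size % target:
        raise ValueError(f"cannot reach {target} from {size} by integer scaling")
    return F.avg_pool_to(x, target)


class TemporalBranch(nn.Module):
    """Stem + ConvLSTM stack + feature head + per-scale channel matching.

    ``skip_channels`` maps downsample factor (2, 4, 8, 16) to the channel
    width the branch must emit at that scale.
    """

    def __init__(self, stem_width: int, hidden: int, layers: int,
                 head_widths: tuple, skip_channels: dict, grid: int = 8,
                 kernel: int = 3, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.grid = grid
        self.stem = nn.Conv2d(1, stem_width, 7, stride=4, padding=3, bias=False,
                              rng=rng, dtype=dtype)
        self.stem_bn = nn.BatchNorm2d(stem_width, dtype=dtype)
        self.lstm = ConvLSTMStack(stem_width, hidden, layers, kernel, rng, dtype)
        self.head = []
        cin = hidden
        for wdt in head_widths:
            self.head.append(nn.Conv2d(cin, wdt, 3, bias=False, rng=rng, dtype=dtype))
            self.head.append(nn.BatchNorm2d(wdt, dtype=dtype))
            cin = wdt
        self.skip_factors = sorted(skip_channels)
        self.match = [nn.Conv2d(cin, skip_channels[f], 1, bias=True, rng=rng, dtype=dtype)
                      for f in self.skip_factors]

    def _grid_size(self, image_size: int) -> int:
        return min(self.grid, image_size // 4)

    def _stem_forward(self, x: Tensor, image_size: int) -> Tensor:
        y = F.relu(self.stem_bn(self.stem(x)))
        return _resize_to(y, self._grid_size(image_size))

    def forward(self, slices) -> dict:
        """slices: list of (N,1,H,W) tensors, oldest first.  Returns a dict
        {downsample factor: (N, C_s, H/f, W/f) temporal feature map}."""
        slices = [x if isinstance(x, Tensor) else Tensor(np.asarray(x)) for x in slices]
        image_size = slices[0].shape[2]
        feats = [self._stem_forward(x, image_size) for x in slices]
        h = self.lstm.run_sequence(feats)
        return temporal_pyramid(h, self, image_size)

    def macs(self, image_size: int, T: int) -> int:
        g = self._grid_size(image_size)
        stem_m, _ = self.stem.macs((image_size, image_size))
        total = T * stem_m
        total += self.lstm.seq_macs((g, g), T)
        for i in range(0, len(self.head), 2):
            total += self.head[i].macs((g, g))[0]
        for conv in self.match:
            total += conv.macs((g, g))[0]
        return total
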
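"""TR-Unet assembly, ablation variants, post-processing and profiling.

The full model runs two branches over a sequence unit: the spatial branch
encodes the target slice x_t into a feature pyramid, and the temporal
branch runs the whole unit through a ConvLSTM stack and emits channel-
matched per-scale temporal features.  At each of the four skip levels the
two are fused and the result feeds the decoder; the output weight map is
the sigmoid of the decoder logits.

Variant semantics (chosen to make the component budgets exactly additive,
mirroring the printed complexity tables):

* full        — skip = CA(fusion_convs(concat(e_s, t_s)))
* -CA         — fusion stack removed; skip = e_s + t_s (parameter-free add)
* -ConvLSTM   — temporal branch removed; the fusion stack is kept intact
                and its temporal input slice receives zeros
* ResUnet     — both removed; skip = e_s (pure spatial encoder-decoder)

Post-processing binarises the weight map, keeps the largest 4-connected
component and fills interior holes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from . import nn
from .backbone import Decoder, Encoder
from .convlstm import TemporalBranch
from .coordattn import CoordinateAttention
from .nn import functional as F
from .nn.tensor import Tensor
from .preprocess import SequenceUnit

SKIP_FACTORS = (2, 4, 8, 16)


@dataclass
class ModelConfig:
    image_size: int = 512
    sequence_length: int = 3
    use_convlstm: bool = True
    use_ca: bool = True
    width_multiplier: float = 1.0
    # spatial branch
    encoder_stem: int = 64
    encoder_mids: tuple = (64, 128, 256, 512)
    encoder_outs: tuple = (256, 512, 1024, 2048)
    decoder_widths: tuple = (1024, 512, 256, 64)   # deepest first
    d0_width: int = 32
    # temporal branch
    temporal_stem: int = 4
    convlstm_hidden: int = 24
    convlstm_layers: int = 2
    temporal_head: tuple = (96, 96)
    temporal_grid: int = 8
    # fusion stack (per skip factor 2, 4, 8, 16)
    fusion_widths: tuple = (192, 448, 256, 64)
    fusion_depth: tuple = (2, 2, 1, 0)
    ca_reduction: int = 16
    calibration_version: str = "uncalibrated"

    def __post_init__(self):
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")
        if self.image_size % 32:
            raise ValueError("image_size must be divisible by 32")

    def scaled(self) -> "ModelConfig":
        """Apply width_multiplier to every channel width (floor of 4)."""
        m = self.width_multiplier
        if m == 1.0:
            return self
        sc = lambda c: max(4, int(round(c * m)))
        return ModelConfig(
            image_size=self.image_size, sequence_length=self.sequence_length,
            use_convlstm=self.use_convlstm, use_ca=self.use_ca,
            width_multiplier=1.0,
            encoder_stem=sc(self.encoder_stem),
            encoder_mids=tuple(sc(c) for c in self.encoder_mids),
            encoder_outs=tuple(sc(c) for c in self.encoder_outs),
            decoder_widths=tuple(sc(c) for c in self.decoder_widths),
            d0_width=sc(self.d0_width),
            temporal_stem=sc(self.temporal_stem),
            convlstm_hidden=sc(self.convlstm_hidden),
            convlstm_layers=self.convlstm_layers,
            temporal_head=tuple(sc(c) for c in self.temporal_head),
            temporal_grid=self.temporal_grid,
            fusion_widths=tuple(sc(c) for c in self.fusion_widths),
            fusion_depth=self.fusion_depth,
            ca_reduction=self.ca_reduction,
            calibration_version=f"{self.calibration_version}/x{m}",
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        for k in ("encoder_mids", "encoder_outs", "decoder_widths",
                  "temporal_head", "fusion_widths", "fusion_depth"):
            d[k] = tuple(d[k])
        return cls(**d)


class FusionBlock(nn.Module):
    """concat(spatial, temporal) -> 1x1 conv -> refinement 3x3 convs ->
    1x1 conv back to the skip width -> coordinate attention."""

    def __init__(self, skip_ch: int, width: int, depth: int, reduction: int,
                 rng=None, dtype=np.float32):
        super().__init__()
        self.skip_ch = skip_ch
        self.inp = nn.Conv2d(2 * skip_ch, width, 1, bias=True, rng=rng, dtype=dtype)
        self.mids = [nn.Conv2d(width, width, 3, bias=True, rng=rng, dtype=dtype)
                     for _ in range(depth)]
        self.out = nn.Conv2d(width, skip_ch, 1, bias=True, rng=rng, dtype=dtype)
        self.ca = CoordinateAttention(skip_ch, reduction, rng=rng, dtype=dtype)

    def forward(self, spatial: Tensor, temporal: Tensor | None) -> Tensor:
        if temporal is None:
            n, c, h, w = spatial.shape
            temporal = Tensor(np.zeros((n, c, h, w), dtype=spatial.dtype))
        y = F.relu(self.inp(F.concat([spatial, temporal], axis=1)))
        for m in self.mids:
            y = F.relu(m(y))
        y = F.relu(self.out(y))
        return self.ca(y)

    def macs(self, hw) -> int:
        total = self.inp.macs(hw)[0]
        for m in self.mids:
            total += m.macs(hw)[0]
        total += self.out.macs(hw)[0]
        total += self.ca.macs(hw)
        return total


class TRUnet(nn.Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        cfg = config.scaled()
        self.config = config
        self.cfg = cfg
        rng = rng or np.random.default_rng(0)
        self.encoder = Encoder(cfg.encoder_stem, cfg.encoder_mids, cfg.encoder_outs,
                               rng=rng, dtype=dtype)
        skip_ch = {2: cfg.encoder_stem, 4: cfg.encoder_outs[0],
                   8: cfg.encoder_outs[1], 16: cfg.encoder_outs[2]}
        # decoder consumes skips deepest first: factors 16, 8, 4, 2
        self.decoder = Decoder(cfg.encoder_outs[3], cfg.decoder_widths,
                               [skip_ch[f] for f in (16, 8, 4, 2)],
                               cfg.d0_width, rng=rng, dtype=dtype)
        self.temporal = None
        if cfg.use_convlstm:
            self.temporal = TemporalBranch(
                cfg.temporal_stem, cfg.convlstm_hidden, cfg.convlstm_layers,
                cfg.temporal_head, skip_ch, grid=cfg.temporal_grid,
                rng=rng, dtype=dtype)
        self.fusion = None
        if cfg.use_ca:
            widths = dict(zip(SKIP_FACTORS, cfg.fusion_widths))
            depths = dict(zip(SKIP_FACTORS, cfg.fusion_depth))
            self.fusion = [FusionBlock(skip_ch[f], widths[f], depths[f],
                                       cfg.ca_reduction, rng=rng, dtype=dtype)
                           for f in SKIP_FACTORS]
        self._skip_ch = skip_ch

    # -- forward ---------------------------------------------------------
    def _slices(self, unit) -> list:
        if isinstance(unit, SequenceUnit):
            stack = unit.stack[None]          # (1, T, C, H, W)
        else:
            stack = np.asarray(unit)
            if stack.ndim == 4:
                stack = stack[None]
        if stack.shape[1] != self.cfg.sequence_length:
            raise ValueError(f"unit length {stack.shape[1]} != "
                             f"configured T={self.cfg.sequence_length}")
        if stack.shape[3] != self.cfg.image_size:
            raise ValueError(f"frame size {stack.shape[3]} != "
                             f"configured image_size={self.cfg.image_size}")
        return [Tensor(np.ascontiguousarray(stack[:, t])) for t in range(stack.shape[1])]

    def forward(self, unit) -> Tensor:
        slices = self._slices(unit)
        pyramid = self.encoder(slices[-1])
        temporal = self.temporal(slices) if self.temporal is not None else None
        fused = []
        fusion_by_factor = dict(zip(SKIP_FACTORS, self.fusion)) if self.fusion else None
        for factor, e_s in pyramid.skips():
            t_s = temporal[factor] if temporal is not None else None
            if fusion_by_factor is not None:
                fused.append(fusion_by_factor[factor](e_s, t_s))
            elif t_s is not None:
                fused.append(F.add(e_s, t_s))
            else:
                fused.append(e_s)
        logits = self.decoder(pyramid.e4, fused)
        return F.sigmoid(logits)

    def predict(self, unit) -> np.ndarray:
        """Eval-mode probability map as a (H, W) numpy array."""
        was_training = self.training
        self.eval()
        try:
            prob = self.forward(unit).data
        finally:
            self.train(was_training)
        return prob[0, 0]

    # -- profiling -------------------------------------------------------
    def component_macs(self, image_size: int | None = None, T: int | None = None) -> dict:
        size = image_size or self.cfg.image_size
        T = T or self.cfg.sequence_length
        hw = (size, size)
        enc, _ = self.encoder.macs(hw)
        dec, _ = self.decoder.macs((size // 32, size // 32))
        out = {"encoder": enc, "decoder": dec}
        if self.temporal is not None:
            out["temporal"] = self.temporal.macs(size, T)
        if self.fusion is not None:
            out["fusion"] = sum(
                blk.macs((size // f, size // f))
                for f, blk in zip(SKIP_FACTORS, self.fusion))
        return out

    def macs(self, image_size: int | None = None, T: int | None = None) -> int:
        return int(sum(self.component_macs(image_size, T).values()))


def build_variant(config: ModelConfig, rng: np.random.Generator | None = None,
                  dtype=np.float32) -> TRUnet:
    return TRUnet(config, rng=rng, dtype=dtype)


def count_params(model: nn.Module) -> int:
    """Total trainable scalars (convolution/transposed-convolution kernels
    and biases, BN affine parameters, ConvLSTM kernels/peepholes/biases,
    attention convolutions).  BN running statistics are not trainable."""
    return model.param_count()


def count_macs(model: TRUnet, image_size: int = 512, T: int = 3) -> int:
    """Analytic multiply-accumulate count of one forward pass.

    Convolutions contribute Cin*Cout*k^2 per output position, transposed
    convolutions per input position, ConvLSTM per-step cost is multiplied
    by T; elementwise ops, BN, activations and pooling are excluded.
    """
    return model.macs(image_size, T)


def postprocess(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarise at ``threshold``, keep the largest 4-connected foreground
    component, fill interior holes.  An empty foreground returns an all-zero
    mask with a warning."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    prob = np.asarray(prob)
    binary = prob > threshold
    if not binary.any():
        warnings.warn("post-processing: empty foreground", stacklevel=2)
        return np.zeros(prob.shape, dtype=np.uint8)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    labels, n = ndimage.label(binary, structure=structure)
    if n > 1:
        sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
        binary = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(binary).astype(np.uint8)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: TRUnet, path, extra: dict | None = None):
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    meta = {"config": json.loads(model.config.to_json()),
            "calibration_version": model.config.calibration_version}
    if extra:
        meta["extra"] = extra
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path, dtype=np.float32) -> TRUnet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = ModelConfig.from_json(json.dumps(meta["config"]))
        model = TRUnet(cfg, rng=np.random.default_rng(0), dtype=dtype)
        model.load_state_dict({k[len("param/"):]: v for k, v in data.items()
                               if k.startswith("param/")})
    return model
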
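"""Analytic complexity profiling of the architecture variants.

Counting convention: a convolution contributes Cin/groups*Cout*k^2 MACs per
output position; a transposed convolution the same per input position; the
ConvLSTM pays its per-step convolution cost once per sequence step (T
total); elementwise operations, batch normalisation, activations and
pooling are free.  Parameters count every trainable scalar.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import calibrated_config
from .model import TRUnet, build_variant, count_macs, count_params

VARIANTS = {
    "-ConvLSTM -CA (ResUnet)": dict(use_convlstm=False, use_ca=False),
    "-CA": dict(use_convlstm=True, use_ca=False),
    "-ConvLSTM": dict(use_convlstm=False, use_ca=True),
    "TR-Unet (full)": dict(use_convlstm=True, use_ca=True),
}


def profile_variants(image_size: int = 512, T: int = 3, seed: int = 0,
                     **config_overrides) -> pd.DataFrame:
    """Params (M) and MACs (G) for the four variants, 2-decimal as printed."""
    rows = []
    for name, flags in VARIANTS.items():
        cfg = calibrated_config(**flags, sequence_length=T, **config_overrides)
        model = build_variant(cfg, rng=np.random.default_rng(seed))
        p = count_params(model)
        g = count_macs(model, image_size, T)
        rows.append({"variant": name,
                     "params": p, "macs": g,
                     "params_M": round(p / 1e6, 2),
                     "macs_G": round(g / 1e9, 2)})
        del model
    return pd.DataFrame(rows)
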
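import numpy as np
import pytest

from trunet.calibration import calibrated_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Smallest usable model: 32-px frames, heavily narrowed widths."""
    return calibrated_config(image_size=32, width_multiplier=0.0625,
                             sequence_length=3)


@pytest.fixture
def desk_config_64():
    return calibrated_config(image_size=64, width_multiplier=0.25,
                             sequence_length=3)
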
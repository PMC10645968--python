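import numpy as np
import pytest

from spikegrain import set_scale
from spikegrain.simulate import SpikeSimConfig, generate_spike_image


@pytest.fixture(scope="session")
def cal10():
    """10 px/mm calibration (100 px line = 10 mm)."""
    return set_scale(100.0, 10.0, global_flag=True)


@pytest.fixture(scope="session")
def rendered_spike():
    """One deterministic 20-row spike: (config, image, truth, scale_bar)."""
    cfg = SpikeSimConfig(seed=42, noise_sd=0.02)
    image, truth, bar = generate_spike_image(cfg)
    return cfg, image, truth, bar


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
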
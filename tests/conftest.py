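import os
import tempfile

import numpy as np
import pytest
from hypothesis import configuration, settings

from odorcap import models

# keep hypothesis scratch (example db, constants cache) out of the repo tree
configuration.set_hypothesis_home_dir(
    os.path.join(tempfile.gettempdir(), "hypothesis-home")
)
settings.register_profile("odorcap", database=None, deadline=None)
settings.load_profile("odorcap")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sigma_rgb():
    """Calibrated color noise SD for jnd=0.01, shared across the session."""
    return models.calibrate_color_noise(0.01, rng=np.random.default_rng(777))


@pytest.fixture(scope="session")
def color_noise(sigma_rgb):
    return models.NoiseConfig(sigma_rgb=sigma_rgb, jnd=0.01)
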
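import numpy as np
import pytest

from tdspec.calibration import ek_calibration
from tdspec.synthetic import calibrant_scene, generate_measurement


@pytest.fixture(scope="session")
def ek_model():
    """The built-in [EK]_N TDS-vs-helical-length calibration."""
    return ek_calibration()


@pytest.fixture(scope="session")
def calibrant_measurement():
    """A noise-free NMA-like calibrant measurement (scene, spectra, truth)."""
    return generate_measurement(calibrant_scene())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
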
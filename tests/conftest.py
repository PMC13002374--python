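import numpy as np
import pytest

from cardiopatch import protocols


@pytest.fixture(scope="session")
def calibrated_hipsc_diffusivity():
    """Base diffusivity yielding the 45 cm/s control CV target (hiPSC cable)."""
    return protocols.calibrate_conductivity("paci_hipsc")


@pytest.fixture(scope="session")
def calibrated_atrial_diffusivity():
    """Base diffusivity yielding the 0.8 m/s atrial-body CV target."""
    return protocols.calibrate_conductivity("courtemanche")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
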
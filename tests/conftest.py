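import numpy as np
import pytest
from hypothesis import settings

from uriscreen import kinetics

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def k_ref():
    """Package-default HIU decay rate at Tris pH 7.4 (calibrated once)."""
    return kinetics.default_k_ref()


@pytest.fixture(scope="session")
def tris_308():
    return kinetics.AssayCondition(buffer="tris", pH=7.4, wavelength_nm=308.0)


@pytest.fixture(scope="session")
def borate_308_ph74():
    return kinetics.AssayCondition(buffer="borate", pH=7.4, wavelength_nm=308.0)


@pytest.fixture(scope="session")
def borate_293_ph92():
    return kinetics.AssayCondition(buffer="borate", pH=9.2, wavelength_nm=293.0)


@pytest.fixture(scope="session")
def calibrated_tris_model(tris_308):
    """Model whose A308 trace peaks at ~100 s under the anchor conditions."""
    return kinetics.calibrate_interference_model(tris_308)


def default_model(condition, activity, km=0.25):
    return kinetics.default_kinetic_model(condition, activity, Km_mM=km)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
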
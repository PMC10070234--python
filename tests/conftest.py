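import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vibexciton as vx
from vibexciton.spectra import TimeGrid

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


#: coarse grid for Q-band-only systems (span +-2048 cm^-1 around the center)
SMALL_GRID = TimeGrid(8192, 1.0 / 4096.0)


@pytest.fixture(scope="session")
def chla_catalog():
    return vx.chla_mode_catalog()


@pytest.fixture(scope="session")
def wscp_config():
    return vx.preset_config("wscp")


@pytest.fixture(scope="session")
def ether_config():
    return vx.preset_config("ether")


@pytest.fixture(scope="session")
def wscp_engine(wscp_config):
    return vx.build_engine(wscp_config)


@pytest.fixture(scope="session")
def wscp_system(wscp_config):
    return vx.build_system(wscp_config)


@pytest.fixture(scope="session")
def ether_engine(ether_config):
    return vx.build_engine(ether_config)


@pytest.fixture(scope="session")
def ether_system(ether_config):
    return vx.build_system(ether_config)


@pytest.fixture(scope="session")
def ether_hom_spectrum(ether_engine, ether_system):
    """Homogeneous monomer absorption/CD spectrum (full model, ether preset)."""
    return ether_engine.spectrum(ether_system)


@pytest.fixture(scope="session")
def wscp_hom_spectrum(wscp_engine, wscp_system):
    """Homogeneous dimer absorption/CD spectrum (full model, WSCP preset)."""
    return wscp_engine.spectrum(wscp_system)


@pytest.fixture(scope="session")
def open_sandwich():
    return vx.make_open_sandwich()


def peak_position(result, lo, hi, signal="absorption"):
    """Frequency of the maximum of a spectrum within a window."""
    y = result.absorption if signal == "absorption" else result.cd
    sel = (result.frequencies >= lo) & (result.frequencies <= hi)
    return float(result.frequencies[sel][np.argmax(y[sel])])
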
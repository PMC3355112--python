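import numpy as np
import pytest

from kvgating import (
    ChannelAssembly,
    PhysicalConstants,
    SubunitKinetics,
    calibrate_from_boltzmann,
)
from kvgating.presets import default_heterotetramer, default_homotetramer


@pytest.fixture(scope="session")
def pc():
    return PhysicalConstants()


@pytest.fixture(scope="session")
def common_kin(pc):
    return calibrate_from_boltzmann(-26.5, 4.6, 16.5, -26.5, pc)


@pytest.fixture(scope="session")
def distinct_kin(pc):
    return calibrate_from_boltzmann(-93.2, 9.4, 5.8, -70.0, pc)


@pytest.fixture(scope="session")
def homo(pc):
    return default_homotetramer(pc)


@pytest.fixture(scope="session")
def hetero(pc):
    return default_heterotetramer(pc)


@pytest.fixture
def simple_kin():
    return SubunitKinetics(alpha0=1.0, beta0=1.0,
                           z_alpha_delta=1.0, z_beta_delta=1.0)


@pytest.fixture
def simple_asm(simple_kin):
    return ChannelAssembly.homotetramer(simple_kin)
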
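import numpy as np
import pytest

from hydrossm.ssm_core import AxisSpec
from hydrossm.synthetic_data import IdealGasSpec, generate_ideal_gas


@pytest.fixture(scope="session")
def small_gas():
    """Small ideal-gas trajectory: rho=33 nm^-3, 4 nm box, 240 frames."""
    return generate_ideal_gas(IdealGasSpec(33.0, (4.0, 4.0, 4.0), 240, seed=11))


@pytest.fixture(scope="session")
def small_gas_spec():
    return IdealGasSpec(33.0, (4.0, 4.0, 4.0), 240, seed=11)


@pytest.fixture
def center_axis():
    return AxisSpec(2.0, 2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
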
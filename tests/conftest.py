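import numpy as np
import pytest

from fibrocircuit import CircuitParameters, find_autocrine_threshold


@pytest.fixture(scope="session")
def wt() -> CircuitParameters:
    return CircuitParameters.wildtype()


@pytest.fixture(scope="session")
def lambda1_scan(wt):
    """Shared 1%-resolution autocrine-weakening scan (used by several tests)."""
    return find_autocrine_threshold(wt, scaled_parameter="lambda1", resolution=0.01)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
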
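import numpy as np
import pytest

from paslquant import AcquisitionParams, KineticParams, PhantomSpec, \
    build_phantom


@pytest.fixture(scope="session")
def acq():
    """Default acquisition: TI1/TI2 = 800/1800 ms, 30 ms slice increment."""
    return AcquisitionParams()


@pytest.fixture(scope="session")
def default_phantom():
    return build_phantom(PhantomSpec(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(20140515)


@pytest.fixture
def kp():
    return KineticParams(cbf=45.0, att=700.0, tau=900.0, m0b=1000.0)
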
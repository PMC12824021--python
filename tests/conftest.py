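import numpy as np
import pytest

from aortivo import fixtures
from aortivo.constitutive import MaterialParams


@pytest.fixture(scope="session")
def exvivo_params():
    return fixtures.load_exvivo_params()


@pytest.fixture(scope="session")
def ad1_params(exvivo_params):
    """Dissection subject AD1's ex vivo coefficients, the package's common
    initial guess."""
    return exvivo_params["AD1"]


@pytest.fixture(scope="session")
def isotropic_params():
    """Fiber contribution switched off: the response must be isotropic."""
    return MaterialParams(c1=5.0, D1=2.0, D2=1.1, K1=0.0, K2=1.0, theta=30.0)


@pytest.fixture(scope="session")
def cohort():
    return fixtures.load_cohort()


@pytest.fixture(scope="session")
def stiffness_table():
    return fixtures.load_stiffness_comparison()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
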
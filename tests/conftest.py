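import numpy as np
import pytest

from pulletgrowth.monomolecular import MonomolecularParams
from pulletgrowth.profiles import observations_to_arrays
from pulletgrowth.synthetic import SyntheticSpec, generate_scaled


@pytest.fixture(scope="session")
def hyline_params() -> MonomolecularParams:
    """Published Hy-Line W36 fit, used for closed-form trait checks."""
    return MonomolecularParams(a=0.0861, b=0.0219, c=2.2129)


@pytest.fixture(scope="session")
def isa_params() -> MonomolecularParams:
    return MonomolecularParams(a=0.1006, b=0.1342, c=3.1921)


@pytest.fixture(scope="session")
def noiseless_xy():
    """18 exact points on the default synthetic curve (a,b,c)=(0.10,0.15,3.5)."""
    spec = SyntheticSpec(noise_sd=0.0, seed=1)
    x, y = observations_to_arrays(generate_scaled(spec))
    return x, y


@pytest.fixture(scope="session")
def c_column():
    """Six-strain (estimate, SE) pairs for the rate parameter c."""
    est = np.array([2.2129, 3.1921, 3.9070, 3.9254, 2.8148, 4.2621])
    se = np.array([0.2001, 0.3771, 0.6134, 0.6343, 0.5592, 0.6419])
    return est, se
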
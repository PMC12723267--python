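import numpy as np
import pytest

from diffdot.datasets import generate_dataset
from diffdot.phantoms import Inclusion, Phantom, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """40-sample dataset shared by training / evaluation tests."""
    return generate_dataset(n=40, seed=7)


@pytest.fixture(scope="session")
def inclusion_phantom():
    return Phantom(
        diameter=60.0,
        background_mu_a=0.006,
        background_mu_s_prime=1.0,
        frequency_mhz=50.0,
        inclusions=(Inclusion((10.0, 5.0), 10.0, 4.0, 2.0),),
    )


@pytest.fixture(scope="session")
def inclusion_measurement(inclusion_phantom):
    return simulate(inclusion_phantom)
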
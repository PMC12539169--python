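import numpy as np
import pytest

from cephalo3d.catalog import catalog_names, phantom_catalog
from cephalo3d.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def phantom_names():
    return catalog_names(phantom_catalog())


@pytest.fixture(scope="session")
def clean_phantom():
    """One noiseless desk-scale phantom shared across tests."""
    return generate_phantom(PhantomConfig(seed=7, noise_sd=0.0))


@pytest.fixture(scope="session")
def tiny_phantom():
    return generate_phantom(PhantomConfig.tiny(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
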
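import numpy as np
import pytest

from bifscan.synthetic_data import SynthConfig, generate


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic study shared across tests."""
    return generate(SynthConfig(n_genes=80, rng_seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
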
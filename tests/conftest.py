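import numpy as np
import pytest

from dimerscope import synthetic


@pytest.fixture(scope="session")
def bundle():
    """Idealised 7-TM coarse-grained bundle in its reference pose."""
    return synthetic.gen_bundle()


@pytest.fixture(scope="session")
def bundle_h8():
    return synthetic.gen_bundle(include_h8=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
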
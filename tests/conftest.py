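import numpy as np
import pytest

from cginverse.fixtures import make_dope_fixture


@pytest.fixture(scope="session")
def dope():
    """(atomistic topology, mapping scheme, CG topology) of the DOPE fixture."""
    return make_dope_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
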
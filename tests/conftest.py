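import numpy as np
import pytest

from bclkit import synthetic_data as sd


@pytest.fixture
def helix20():
    return sd.make_helix(sd.HelixSpec(n_residues=20))


@pytest.fixture
def helix60():
    return sd.make_helix(sd.HelixSpec(n_residues=60))


@pytest.fixture
def bundle():
    return sd.make_bundle(n_helices=4, helix_length=15)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
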
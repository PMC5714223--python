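import numpy as np
import pytest

from turboalign.fixtures import default_family_spec, generate_family
from turboalign.pair_hmm import default_hmm_parameters


@pytest.fixture(scope="session")
def hmm_params():
    return default_hmm_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_family():
    """A 3-sequence family small enough for fast end-to-end tests."""
    spec = default_family_spec(5, n_seqs=3)
    return generate_family(spec)
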
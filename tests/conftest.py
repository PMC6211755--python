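import numpy as np
import pytest

from btchar import synthetic


@pytest.fixture()
def rng():
    return np.random.default_rng(20181101)


@pytest.fixture(scope="session")
def small_family():
    """A 4-member homolog family with 8 recorded substitutions per member."""
    family, truth = synthetic.make_reference_family(150, 4, 8, seed=7)
    return family, truth
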
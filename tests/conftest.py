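import numpy as np
import pytest

from treeweb.design import enumerate_combinations
from treeweb.synthetic_data import generate_design


@pytest.fixture(scope="session")
def full_design():
    """16-species broken-stick design: 31 plots, 400 sample records."""
    return generate_design(16, seed=7)


@pytest.fixture(scope="session")
def full_combos(full_design):
    design, _ = full_design
    return enumerate_combinations(design)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
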
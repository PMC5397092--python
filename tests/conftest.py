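import numpy as np
import pytest

from celldecide import tnf_nfkb_dataset


@pytest.fixture(scope="session")
def fixture_table():
    """The packaged synthetic two-genotype dose-response dataset."""
    return tnf_nfkb_dataset(cells_per_condition=500, seed=2021)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
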
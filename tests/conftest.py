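import numpy as np
import pytest
from hypothesis import settings

from lipochemo import dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def table1():
    return dataset.load_table1()


@pytest.fixture(scope="session")
def table2():
    return dataset.load_table2()


@pytest.fixture(scope="session")
def panel():
    return dataset.lipophilicity_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(20220621)
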
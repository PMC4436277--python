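import pytest

from uvealcea.lifetable import LifeTable, bundled_life_table
from uvealcea.params import default_parameters


@pytest.fixture(scope="session")
def bundle():
    return default_parameters()


@pytest.fixture(scope="session")
def life():
    return bundled_life_table()


@pytest.fixture
def flat_life():
    """Constant 0.9% annual background mortality over the model ages."""
    return LifeTable(tuple(range(59, 70)), (0.009,) * 11)


@pytest.fixture
def zero_life():
    """No background mortality (isolates disease dynamics)."""
    return LifeTable(tuple(range(59, 70)), (0.0,) * 11)
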
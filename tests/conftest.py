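import pytest

from immune_exposure import (
    SourceCompatibilityMap,
    default_matrix,
    default_term_table,
    default_vocabulary,
    table2_fixtures,
)


@pytest.fixture(scope="session")
def vocabulary():
    return default_vocabulary()


@pytest.fixture(scope="session")
def matrix():
    return default_matrix()


@pytest.fixture(scope="session")
def term_table():
    return default_term_table()


@pytest.fixture(scope="session")
def compat():
    return SourceCompatibilityMap.default()


@pytest.fixture(scope="session")
def table2():
    return table2_fixtures()
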
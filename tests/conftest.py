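import pytest

from pase import load_packaged_table, normalize


@pytest.fixture(scope="session")
def table():
    return load_packaged_table()


@pytest.fixture(scope="session")
def ntable(table):
    """Calibrated default space (raw values, global-max scaling)."""
    return normalize(table)


@pytest.fixture(scope="session")
def ntable_minmax(table):
    return normalize(table, scheme="minmax-global-max")
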
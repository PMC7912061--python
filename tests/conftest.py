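import pytest

from snailpep import default_mass_table, default_reference, load_table1


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def reference():
    return default_reference()


@pytest.fixture(scope="session")
def mass_table():
    return default_mass_table()
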
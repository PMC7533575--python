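import pytest

from lassomine.synthetic import load_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Packaged presence matrix, precursor table, and anchor panel."""
    return load_fixtures()


@pytest.fixture(scope="session")
def presence_matrix(fixtures):
    return fixtures[0]


@pytest.fixture(scope="session")
def precursor_table(fixtures):
    return fixtures[1]


@pytest.fixture(scope="session")
def anchor_panel(fixtures):
    return fixtures[2]
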
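import pytest

from coffeetide.datasets import FIG3_CONNECTIVITY, load_table, table_peptides


@pytest.fixture(scope="session")
def table():
    return load_table()


@pytest.fixture(scope="session")
def peptides():
    """All mature table peptides, oxidized (4 disulfides)."""
    return table_peptides(n_disulfides=4)


@pytest.fixture(scope="session")
def cc1a(peptides):
    return peptides["cC1a"]


@pytest.fixture(scope="session")
def fig3_connectivity():
    return FIG3_CONNECTIVITY
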
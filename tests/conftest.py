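import pytest

from locuskit.star import ActivityTable, load_default_definitions
from locuskit.synthetic import make_gene_references


@pytest.fixture(scope="session")
def gene_refs():
    """Surrogate CYP paralog reference set at the default 5% divergence."""
    return make_gene_references(seed=7)


@pytest.fixture(scope="session")
def packaged_star():
    """(reference, definitions, exon intervals) from the packaged surrogate."""
    return load_default_definitions()


@pytest.fixture(scope="session")
def activity_table():
    return ActivityTable.default()
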
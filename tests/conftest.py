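import pytest

from novapipe.synthetic_data import FixtureConfig, SimConfig, make_fixture, simulate_reads


@pytest.fixture(scope="session")
def fixture():
    """Default toy fixture: crh-1-like A3'SS locus, shared gene, plain circ
    hosts and one gene per linear event class."""
    return make_fixture(FixtureConfig(seed=101))


@pytest.fixture(scope="session")
def sim(fixture):
    """Reads + recorded truth under the default study conditions
    (2 genotypes x 5 replicates, 150-nt pairs, phi = 0.05, 10% duplicates)."""
    return simulate_reads(fixture, SimConfig(seed=202))


@pytest.fixture(scope="session")
def small_fixture_config():
    """A two-gene layout for Monte-Carlo loops where speed matters."""
    return FixtureConfig(seed=303, n_plain_circ_genes=1, n_shared_genes=0,
                         splice_gene_types=())
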
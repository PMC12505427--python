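import pytest

from endosym.genome_io import NucleotideGenome
from endosym.pathways import load_catalog, load_presence_fixture
from endosym.simulate import SimulationConfig, plant_split_genes, simulate_genome


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def presence():
    return load_presence_fixture()


@pytest.fixture(scope="session")
def small_sim():
    """A 60 kb AT-rich genome with 55 intact genes (no splits planted)."""
    cfg = SimulationConfig(seed=11, genome_length=60_000, gc_target=0.20, n_genes=55)
    return simulate_genome(cfg)


@pytest.fixture(scope="session")
def split_sim(small_sim):
    """The small genome with 8 planted split genes plus the planting truth."""
    genome, features, _ = small_sim
    return plant_split_genes(genome, features, 8, seed=13)


def make_genome(seq: str, circular: bool = False, gid: str = "g1") -> NucleotideGenome:
    return NucleotideGenome(gid, seq, circular=circular)
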
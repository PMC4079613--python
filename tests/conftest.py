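import pytest

from mitocode.alignment import build_codon_alignment
from mitocode.genome_io import concatenated_pcgs
from mitocode.simulate import default_config, simulate


@pytest.fixture(scope="session")
def sim():
    """One default 12-taxon simulation shared across the suite."""
    genomes, truth = simulate(default_config(0))
    return genomes, truth


@pytest.fixture(scope="session")
def sim_alignment(sim):
    genomes, _truth = sim
    return build_codon_alignment({g.id: concatenated_pcgs(g) for g in genomes})
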
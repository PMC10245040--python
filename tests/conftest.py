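import pytest

from svjunction import simdata as sim
from svjunction import sv_panel as sp


@pytest.fixture(scope="session")
def sim_genome():
    """Toy genome with 4 planted SVs covering all orientation combinations."""
    return sim.make_genome_with_svs(seed=3, n_svs=4)


@pytest.fixture(scope="session")
def junctions(sim_genome):
    return [sp.build_junction_reference(c, sim_genome.reference) for c in sim_genome.calls]


@pytest.fixture(scope="session")
def amplicon_panel(junctions):
    return sim.design_panel(junctions)
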
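import pytest

from regevo import study
from regevo.phylo import SpeciesTree
from regevo.simulate import SimConfig, simulate_world


@pytest.fixture(scope="session")
def default_world():
    """One default 20-taxon synthetic study, shared across tests."""
    return simulate_world(SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_consensus(default_world):
    return study.all_consensus(default_world)


@pytest.fixture(scope="session")
def fixture_tree():
    return SpeciesTree.default()


@pytest.fixture(scope="session")
def anchor_calls(default_world, default_consensus):
    calls, anchor_els = study.anchor_call_table(
        default_world, "human", default_consensus)
    return calls, anchor_els
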
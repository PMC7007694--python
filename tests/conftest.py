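import networkx as nx
import numpy as np
import pytest

from seednet.genesets import GeneSet
from seednet.interactome import InteractionNetwork
from seednet.synthetic_data import SimulationConfig


def make_network(edges):
    """Build an InteractionNetwork from (a, b, coexpr) triples."""
    graph = nx.Graph()
    for a, b, coexpr in edges:
        graph.add_edge(a, b, ppi=True, coexpr=coexpr)
    return InteractionNetwork(graph)


@pytest.fixture
def toy_interactome():
    """The hand-traced extraction fixture.

    Edges: A-B(both), A-C(both), C-D(ppi only), D-E(both).
    """
    return make_network(
        [("A", "B", True), ("A", "C", True), ("C", "D", False), ("D", "E", True)]
    )


@pytest.fixture
def small_sim_config():
    return SimulationConfig(
        n_genes=300,
        n_deg=40,
        n_coexpr_blocks=4,
        block_size=15,
        seed_set_sizes={"asd": 40, "ep": 30, "lm": 35},
        n_pathways=20,
        planted_enriched_pathways=3,
        pathway_size_range=(15, 40),
        rng_seed=11,
    )


@pytest.fixture
def random_seed_geneset():
    def _make(nodes, size, seed):
        rng = np.random.default_rng(seed)
        picked = rng.choice(sorted(nodes), size=size, replace=False)
        return GeneSet.from_symbols("random", picked, normalize=False)

    return _make
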
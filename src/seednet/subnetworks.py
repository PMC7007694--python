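"""Seed-subnetwork extraction, permutation nulls, hub ranking, convergence.

Extraction rule: the subnetwork contains the seeds present in the
interactome plus any first neighbor reached from a seed through a
dual-support edge (ppi AND coexpr). Edges are then *induced*: every
interactome edge among the retained nodes appears, including PPI-only
edges, and nodes left with degree zero are pruned.

The null model permutes node labels on the fixed topology (support
flags travel with the edges) and re-extracts for the same seed list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from seednet.genesets import GeneSet
from seednet.interactome import InteractionNetwork


@dataclass
class Subnetwork:
    """Extracted subgraph with node roles (seed/neighbor) and regulation."""

    graph: nx.Graph
    roles: dict[str, str]
    regulation: dict[str, str]
    seed_set_name: str

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def seeds(self) -> set[str]:
        return {n for n, r in self.roles.items() if r == "seed"}


@dataclass
class NullDistribution:
    """Node-shuffle null for one seed set on one interactome."""

    replicate_node_counts: list[int]
    replicate_edge_counts: list[int]
    observed_nodes: int
    observed_edges: int
    reps: int
    rng_seed: int
    empirical_p_nodes: float = field(init=False)
    empirical_p_edges: float = field(init=False)
    degenerate: bool = field(init=False)

    def __post_init__(self) -> None:
        if len(self.replicate_node_counts) != self.reps:
            raise ValueError("replicate count mismatch")
        nodes = np.asarray(self.replicate_node_counts)
        edges = np.asarray(self.replicate_edge_counts)
        # add-one (phantom replicate) estimator keeps p in (0, 1]
        self.empirical_p_nodes = float(
            (1 + (nodes >= self.observed_nodes).sum()) / (self.reps + 1)
        )
        self.empirical_p_edges = float(
            (1 + (edges >= self.observed_edges).sum()) / (self.reps + 1)
        )
        self.degenerate = bool(len(set(self.replicate_node_counts)) <= 1)
        if self.degenerate:
            warnings.warn("degenerate null: all replicate node counts identical")


def _dual_neighbors(graph: nx.Graph, seeds_in: set[str]) -> set[str]:
    recruited: set[str] = set()
    for s in seeds_in:
        for v, data in graph[s].items():
            if data.get("coexpr", False) and data.get("ppi", True):
                recruited.add(v)
    return recruited - seeds_in


def _extract_counts(graph: nx.Graph, seed_genes: set[str]) -> tuple[int, int]:
    """Node/edge counts of the extraction, without building a Subnetwork."""
    seeds_in = seed_genes & set(graph.nodes)
    nodes = seeds_in | _dual_neighbors(graph, seeds_in)
    sub = graph.subgraph(nodes)
    kept = [n for n in sub.nodes if sub.degree(n) > 0]
    return len(kept), sub.subgraph(kept).number_of_edges()


def extract_seed_subnetwork(
    interactome: InteractionNetwork, seeds: GeneSet
) -> Subnetwork:
    """Extract the dual-support seed subnetwork for one seed list.

    Recruitment requires a dual-support (ppi AND coexpr) edge from a
    seed; induced edges afterwards include PPI-only edges. Zero-degree
    nodes (including isolated seeds) are pruned.
    """
    graph = interactome.graph
    seeds_in = set(seeds.genes) & set(graph.nodes)
    if not seeds_in:
        warnings.warn(f"no seed of {seeds.name!r} present in the interactome")
    nodes = seeds_in | _dual_neighbors(graph, seeds_in)
    sub = graph.subgraph(nodes)
    kept = {n for n in sub.nodes if sub.degree(n) > 0}
    out = nx.Graph()
    out.add_nodes_from(kept)
    for u, v, data in sub.edges(data=True):
        if u in kept and v in kept:
            out.add_edge(u, v, ppi=data.get("ppi", True), coexpr=data.get("coexpr", False))
    roles = {n: ("seed" if n in seeds_in else "neighbor") for n in kept}
    regulation = {n: seeds.regulation(n) for n in kept}
    return Subnetwork(
        graph=out, roles=roles, regulation=regulation, seed_set_name=seeds.name
    )


def shuffle_null(
    interactome: InteractionNetwork,
    seeds: GeneSet,
    reps: int = 1000,
    rng_seed: int = 0,
) -> NullDistribution:
    """Node-label permutation null for subnetwork size.

    Each replicate applies a uniform random permutation pi to the node
    labels of the fixed topology and re-extracts for the same seed
    list; this is realized as extraction with the pre-image seed set
    {v : pi(v) in seeds}, which leaves support flags on the topology.
    Per-replicate RNG streams are derived from ``rng_seed`` by counter,
    so results are independent of execution order.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    graph = interactome.graph
    node_list = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(node_list)}
    seed_idx = np.array(
        sorted(index[g] for g in set(seeds.genes) & set(node_list)), dtype=np.intp
    )
    obs_nodes, obs_edges = _extract_counts(graph, set(seeds.genes))
    node_counts: list[int] = []
    edge_counts: list[int] = []
    n = len(node_list)
    for rep in range(reps):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=rng_seed, spawn_key=(rep,))
        )
        perm = rng.permutation(n)
        # pi(node_list[i]) = node_list[perm[i]]; pre-image of the seed
        # label set is {node_list[i] : perm[i] in seed_idx}
        mask = np.zeros(n, dtype=bool)
        mask[seed_idx] = True
        pre_image = {node_list[i] for i in np.flatnonzero(mask[perm])}
        n_nodes, n_edges = _extract_counts(graph, pre_image)
        node_counts.append(n_nodes)
        edge_counts.append(n_edges)
    return NullDistribution(
        replicate_node_counts=node_counts,
        replicate_edge_counts=edge_counts,
        observed_nodes=obs_nodes,
        observed_edges=obs_edges,
        reps=reps,
        rng_seed=rng_seed,
    )


def betweenness_ranking(subnetwork, k: int = 10) -> list[tuple[str, float]]:
    """Top-k nodes by unnormalized shortest-path betweenness.

    Ties break by descending degree, then lexicographic symbol. Accepts
    a :class:`Subnetwork` or a bare graph.
    """
    graph = subnetwork.graph if isinstance(subnetwork, Subnetwork) else subnetwork
    if graph.number_of_nodes() == 0:
        raise ValueError("empty subnetwork")
    if k > graph.number_of_nodes():
        warnings.warn(
            f"k={k} exceeds node count {graph.number_of_nodes()}; returning all"
        )
        k = graph.number_of_nodes()
    bc = nx.betweenness_centrality(graph, normalized=False)
    ranked = sorted(
        bc.items(), key=lambda item: (-item[1], -graph.degree(item[0]), item[0])
    )
    return [(gene, float(val)) for gene, val in ranked[:k]]


def overlap_counts(subnetworks: list[Subnetwork]) -> dict[tuple[str, ...], int]:
    """Venn table: node-overlap count for every combination of inputs."""
    from itertools import combinations

    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(subnetworks) + 1):
        for combo in combinations(subnetworks, r):
            names = tuple(s.seed_set_name for s in combo)
            shared = set.intersection(*(s.nodes for s in combo))
            out[names] = len(shared)
    return out


def converged_module(
    subnetworks: list[Subnetwork], interactome: InteractionNetwork
) -> Subnetwork:
    """Module shared by all subnetworks: node intersection, induced edges.

    Unlike seed extraction, zero-degree nodes are *kept* here — the
    shared node list is the finding even when a node has no induced
    edge.
    """
    if len(subnetworks) < 2:
        raise ValueError("need at least 2 subnetworks")
    shared = set.intersection(*(s.nodes for s in subnetworks))
    graph = nx.Graph()
    graph.add_nodes_from(shared)
    for u, v, data in interactome.graph.subgraph(shared).edges(data=True):
        graph.add_edge(u, v, ppi=data.get("ppi", True), coexpr=data.get("coexpr", False))
    roles = {}
    regulation = {}
    for n in shared:
        member_roles = {s.roles.get(n, "neighbor") for s in subnetworks}
        roles[n] = "seed" if "seed" in member_roles else "neighbor"
        regs = {s.regulation.get(n, "none") for s in subnetworks} - {"none"}
        regulation[n] = regs.pop() if len(regs) == 1 else "none"
    name = "converged(" + "&".join(s.seed_set_name for s in subnetworks) + ")"
    return Subnetwork(
        graph=graph, roles=roles, regulation=regulation, seed_set_name=name
    )
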
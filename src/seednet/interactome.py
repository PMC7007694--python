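"""Tissue interactome construction.

The tissue interactome is the PPI graph restricted to the expressed-gene
universe, cleaned (duplicates collapsed, self-loops removed, zero-degree
nodes pruned) and annotated with co-expression support. Co-expression is
an edge *attribute*, never an edge source: every edge has ppi=True.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import networkx as nx

from seednet.expression import CoexpressionEdgeSet
from seednet.genesets import GeneSet
from seednet.io_formats import EdgeRecord


class InteractionNetwork:
    """Undirected gene graph whose edges carry {ppi, coexpr} support flags."""

    def __init__(self, graph: nx.Graph, provenance: dict | None = None):
        loops = list(nx.selfloop_edges(graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:5]}")
        isolated = [n for n, d in graph.degree() if d == 0]
        if isolated:
            raise ValueError(f"zero-degree nodes not allowed: {isolated[:5]}")
        for u, v, data in graph.edges(data=True):
            data.setdefault("ppi", True)
            data.setdefault("coexpr", False)
            if not data["ppi"]:
                raise ValueError(f"edge without ppi support: {(u, v)}")
        self.graph = graph
        self.provenance = dict(provenance or {})

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def summary(self) -> dict:
        n_dual = sum(1 for _, _, d in self.graph.edges(data=True) if d["coexpr"])
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_dual_support_edges": n_dual,
            **self.provenance,
        }


def build_tissue_interactome(
    ppi_records: Iterable[EdgeRecord], expressed: GeneSet
) -> InteractionNetwork:
    """Restrict a PPI edge list to the expressed universe and clean it.

    Keeps an edge iff both endpoints are expressed, collapses duplicate
    rows (either orientation) to one undirected edge, drops self-loops,
    and prunes nodes left with degree zero.
    """
    ppi_records = list(ppi_records)
    universe = set(expressed.genes)
    graph = nx.Graph()
    n_dup = n_self = n_unexpressed = 0
    for rec in ppi_records:
        a, b = rec.gene_a, rec.gene_b
        if a == b:
            n_self += 1
            continue
        if a not in universe or b not in universe:
            n_unexpressed += 1
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            continue
        graph.add_edge(a, b, ppi=True, coexpr=False)
    # graph only ever gains nodes through edges, so no isolated cleanup
    # is needed beyond nodes that never made it in.
    if graph.number_of_edges() == 0:
        warnings.warn("expressed universe and PPI share no usable edges")
    provenance = {
        "input_records": len(ppi_records),
        "duplicate_records_collapsed": n_dup,
        "self_loops_dropped": n_self,
        "records_outside_universe": n_unexpressed,
    }
    return InteractionNetwork(graph, provenance)


def annotate_coexpression(
    network: InteractionNetwork, coexpr_edges: CoexpressionEdgeSet
) -> InteractionNetwork:
    """Set coexpr=True on every PPI edge present in the co-expression set.

    Topology is unchanged; returns a new network.
    """
    graph = network.graph.copy()
    for u, v, data in graph.edges(data=True):
        data["coexpr"] = (u, v) in coexpr_edges
    return InteractionNetwork(graph, dict(network.provenance))
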
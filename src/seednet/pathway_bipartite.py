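"""Gene-pathway bipartite networks and over-representation filtering.

Pathways are kept when they are over-represented for seed genes at a
one-sided hypergeometric p < 1e-6 AND contain at least ten seed genes.
The enrichment universe defaults to the genes present in the bipartite
network, with the option of an explicit (e.g. full expressed) universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy import stats

from seednet.genesets import GeneSet
from seednet.io_formats import GmtRecord

P_CUT_DEFAULT = 1e-6
MIN_HITS_DEFAULT = 10


@dataclass
class PathwayBipartite:
    """Two-mode gene-pathway membership graph (no within-mode edges)."""

    memberships: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [p for p, members in self.memberships.items() if not members]
        if empty:
            raise ValueError(f"pathway nodes without members: {empty[:5]}")

    @property
    def pathway_nodes(self) -> set[str]:
        return set(self.memberships)

    @property
    def gene_nodes(self) -> set[str]:
        out: set[str] = set()
        for members in self.memberships.values():
            out |= members
        return out

    @property
    def membership_edges(self) -> set[tuple[str, str]]:
        return {
            (gene, pathway)
            for pathway, members in self.memberships.items()
            for gene in members
        }

    @property
    def n_edges(self) -> int:
        return sum(len(m) for m in self.memberships.values())

    def gene_degree(self, gene: str) -> int:
        return sum(1 for members in self.memberships.values() if gene in members)


@dataclass
class PathwayEnrichmentRow:
    """Per-pathway over-representation result against one seed set."""

    pathway_id: str
    pathway_size: int  # m, within the universe
    seed_hits: int  # x
    seeds_in_universe: int  # n
    universe_size: int  # N
    p_hyper: float
    kept: bool


def build_bipartite(
    gmt_records: Iterable[GmtRecord], universe: GeneSet
) -> PathwayBipartite:
    """Restrict pathway memberships to the universe; drop emptied pathways."""
    uni = universe.genes if isinstance(universe, GeneSet) else frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    memberships: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for rec in gmt_records:
        members = rec.members & uni
        if members:
            memberships[rec.pathway_id] = members
            descriptions[rec.pathway_id] = rec.description
    return PathwayBipartite(memberships=memberships, descriptions=descriptions)


def hypergeom_tail(x: int, N: int, m: int, n: int) -> float:
    """One-sided over-representation p = P(X >= x), X ~ Hypergeom(N, m, n)."""
    if x < 0 or m < 0 or n < 0 or N < 1 or x > min(m, n) or m > N or n > N:
        raise ValueError(f"inconsistent hypergeometric counts x={x} N={N} m={m} n={n}")
    return float(stats.hypergeom.sf(x - 1, N, m, n))


def pathway_enrichment(
    bipartite: PathwayBipartite,
    seeds: GeneSet,
    p_cut: float = P_CUT_DEFAULT,
    min_hits: int = MIN_HITS_DEFAULT,
    universe: GeneSet | None = None,
) -> list[PathwayEnrichmentRow]:
    """One-sided hypergeometric over-representation per pathway.

    Population N = genes in the bipartite network (or the explicit
    ``universe``); successes m = pathway size within N; draws n = seeds
    within N; kept iff p < ``p_cut`` and hits >= ``min_hits``.
    """
    uni = bipartite.gene_nodes if universe is None else set(universe.genes)
    seed_genes = set(seeds.genes)
    outside = seed_genes - uni
    if outside:
        warnings.warn(
            f"{len(outside)} seed genes of {seeds.name!r} outside the universe; dropped"
        )
        seed_genes &= uni
    N = len(uni)
    n = len(seed_genes)
    rows: list[PathwayEnrichmentRow] = []
    for pathway_id in sorted(bipartite.memberships):
        members = bipartite.memberships[pathway_id] & uni
        m = len(members)
        x = len(members & seed_genes)
        p = hypergeom_tail(x, N, m, n)
        rows.append(
            PathwayEnrichmentRow(
                pathway_id=pathway_id,
                pathway_size=m,
                seed_hits=x,
                seeds_in_universe=n,
                universe_size=N,
                p_hyper=p,
                kept=bool(p < p_cut and x >= min_hits),
            )
        )
    return rows


def bipartite_subnetwork(
    bipartite: PathwayBipartite,
    rows: Sequence[PathwayEnrichmentRow],
    seeds: GeneSet,
) -> PathwayBipartite:
    """Restrict to kept pathways and their seed-gene members."""
    kept_ids = {row.pathway_id for row in rows if row.kept}
    seed_genes = set(seeds.genes)
    memberships = {
        pid: bipartite.memberships[pid] & seed_genes
        for pid in kept_ids
        if bipartite.memberships[pid] & seed_genes
    }
    descriptions = {pid: bipartite.descriptions.get(pid, "") for pid in memberships}
    return PathwayBipartite(memberships=memberships, descriptions=descriptions)


def converged_pathway_module(
    subnetworks: Sequence[PathwayBipartite],
) -> tuple[PathwayBipartite, list[tuple[str, int]]]:
    """Module shared by all bipartite subnetworks, plus hub genes.

    Pathway nodes = intersection of kept-pathway sets; gene nodes =
    intersection of gene-node sets; membership edges induced. Hub genes
    are ranked by the number of shared pathways they connect to.
    """
    if len(subnetworks) < 2:
        raise ValueError("need at least 2 bipartite subnetworks")
    shared_pathways = set.intersection(*(s.pathway_nodes for s in subnetworks))
    shared_genes = set.intersection(*(s.gene_nodes for s in subnetworks))
    memberships: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for pid in shared_pathways:
        members = frozenset(
            set.intersection(*(set(s.memberships[pid]) for s in subnetworks))
            & shared_genes
        )
        if members:
            memberships[pid] = members
            for s in subnetworks:
                if pid in s.descriptions:
                    descriptions[pid] = s.descriptions[pid]
                    break
    module = PathwayBipartite(memberships=memberships, descriptions=descriptions)
    hubs = sorted(
        ((g, module.gene_degree(g)) for g in module.gene_nodes),
        key=lambda item: (-item[1], item[0]),
    )
    return module, hubs


def pathway_list_overlap(list_a, list_b) -> tuple[int, int, float]:
    """Concordance of pathway id lists: (|a|, |a&b|, 100*|a&b|/|a| to 1 dp)."""
    set_a, set_b = set(list_a), set(list_b)
    if not set_a:
        raise ValueError("empty reference pathway list")
    n_overlap = len(set_a & set_b)
    return len(set_a), n_overlap, round(100.0 * n_overlap / len(set_a), 1)
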
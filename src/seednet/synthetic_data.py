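"""Synthetic inputs with the statistical structure the pipeline assumes.

Generates a scale-free (or Erdos-Renyi) PPI edge list, a small
negative-binomial count matrix with correlated co-expression blocks and
planted differential expression, seed gene sets with a planted
enrichment odds ratio among the planted DEGs, and GMT pathway
annotations with planted over-represented pathways — everything fully
deterministic under ``rng_seed``.

Correlation is induced with a Gaussian copula: genes in a block share a
latent factor with loading sqrt(rho), so the latent pairwise
correlation equals ``within_block_correlation`` and the NB counts
inherit it up to quantile-transform attenuation. Genes within a block
share the same marginal mean, so rho=1 yields byte-identical profiles
(sample Pearson r = 1 wherever profiles are non-constant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from seednet.expression import ExpressionMatrix
from seednet.genesets import GeneSet
from seednet.io_formats import EdgeRecord, GmtRecord

_STAGE_KEYS = {"ppi": 11, "expression": 23, "seed_sets": 37, "pathways": 53}


def _rng(rng_seed: int, stage: str, sub: int = 0) -> np.random.Generator:
    """Per-stage RNG stream derived from the master seed by fixed keys."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=rng_seed, spawn_key=(_STAGE_KEYS[stage], sub))
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 1200
    n_samples_per_group: int = 3  # 2 groups -> 6 columns by default
    ppi_model: str = "scale_free"
    ppi_mean_degree: float = 4.0
    n_coexpr_blocks: int = 10
    block_size: int = 20
    within_block_correlation: float = 0.9
    n_deg: int = 150
    lfc_mean: float = 1.5
    dispersion: float = 5.0
    seed_set_sizes: dict = field(
        default_factory=lambda: {"asd": 120, "ep": 100, "lm": 110}
    )
    planted_enrichment_odds: float = 3.0
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (20, 60)
    planted_enriched_pathways: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be positive")
        if self.ppi_model not in ("scale_free", "erdos_renyi"):
            raise ValueError(f"unknown ppi_model {self.ppi_model!r}")
        if not 0 < self.ppi_mean_degree < self.n_genes:
            raise ValueError("ppi_mean_degree must be in (0, n_genes)")
        if not 0.0 <= self.within_block_correlation <= 1.0:
            raise ValueError("within_block_correlation must be in [0, 1]")
        if self.n_coexpr_blocks * self.block_size > self.n_genes:
            raise ValueError("co-expression blocks exceed the gene universe")
        if self.n_deg < 0 or self.n_deg > self.n_genes:
            raise ValueError("n_deg must be in [0, n_genes]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for name, size in self.seed_set_sizes.items():
            if size < 1 or size > self.n_genes:
                raise ValueError(f"seed set {name!r}: size outside [1, n_genes]")
        if self.planted_enrichment_odds < 1:
            raise ValueError("planted_enrichment_odds must be >= 1")
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi <= self.n_genes:
            raise ValueError("infeasible pathway_size_range")
        if not 0 <= self.planted_enriched_pathways <= self.n_pathways:
            raise ValueError("planted_enriched_pathways must be <= n_pathways")

    def with_seed(self, rng_seed: int) -> "SimulationConfig":
        return replace(self, rng_seed=rng_seed)


def gene_symbols(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def planted_degs(config: SimulationConfig) -> GeneSet:
    """The planted differentially expressed genes (first n_deg symbols).

    All planted genes shift the group-2 mean by 2**lfc_mean, so the
    regulation label follows the sign of lfc_mean.
    """
    symbols = gene_symbols(config.n_genes)[: config.n_deg]
    label = "up" if config.lfc_mean >= 0 else "down"
    return GeneSet(
        name="deg",
        genes=frozenset(symbols),
        labels={g: label for g in symbols},
    )


def simulate_ppi(config: SimulationConfig) -> list[EdgeRecord]:
    """Synthetic undirected PPI edge list over the gene universe.

    ``scale_free`` uses preferential attachment with
    m = round(mean_degree / 2); ``erdos_renyi`` draws exactly
    n * mean_degree / 2 edges uniformly.
    """
    symbols = gene_symbols(config.n_genes)
    rng_seed = int(_rng(config.rng_seed, "ppi").integers(2**31 - 1))
    if config.ppi_model == "scale_free":
        m = max(1, round(config.ppi_mean_degree / 2))
        graph = nx.barabasi_albert_graph(config.n_genes, m, seed=rng_seed)
    else:
        n_edges = round(config.n_genes * config.ppi_mean_degree / 2)
        graph = nx.gnm_random_graph(config.n_genes, n_edges, seed=rng_seed)
    return [
        EdgeRecord(symbols[u], symbols[v], "synthetic")
        for u, v in sorted((min(u, v), max(u, v)) for u, v in graph.edges())
    ]


def _block_assignment(config: SimulationConfig) -> np.ndarray:
    """Block index per gene (-1 = no block); blocks fill the front genes."""
    blocks = np.full(config.n_genes, -1, dtype=int)
    for b in range(config.n_coexpr_blocks):
        start = b * config.block_size
        blocks[start : start + config.block_size] = b
    return blocks


def simulate_expression(config: SimulationConfig) -> ExpressionMatrix:
    """NB counts with Gaussian-copula block correlation and planted DEGs.

    The first ``n_deg`` genes get a group-2 mean shift of
    2**lfc_mean; FPKM is derived from counts, synthetic gene lengths
    (uniform 500-5000 bp) and per-sample library sizes.
    """
    rng = _rng(config.rng_seed, "expression")
    n = config.n_genes
    n_samples = 2 * config.n_samples_per_group
    symbols = gene_symbols(n)
    samples = [f"wt_{i+1}" for i in range(config.n_samples_per_group)] + [
        f"mut_{i+1}" for i in range(config.n_samples_per_group)
    ]
    groups = {s: ("wt" if s.startswith("wt") else "mut") for s in samples}

    lengths = pd.Series(rng.integers(500, 5001, size=n), index=symbols, name="length")
    blocks = _block_assignment(config)
    # per-block shared base mean; independent genes get their own
    block_means = rng.lognormal(mean=math.log(100.0), sigma=1.0, size=max(
        config.n_coexpr_blocks, 1
    ))
    gene_means = rng.lognormal(mean=math.log(100.0), sigma=1.0, size=n)
    base_mu = np.where(blocks >= 0, block_means[np.clip(blocks, 0, None)], gene_means)

    mu = np.tile(base_mu[:, None], (1, n_samples)).astype(float)
    if config.n_deg:
        mu[: config.n_deg, config.n_samples_per_group :] *= 2.0**config.lfc_mean

    rho = config.within_block_correlation
    factors = rng.standard_normal((max(config.n_coexpr_blocks, 1), n_samples))
    noise = rng.standard_normal((n, n_samples))
    z = np.where(
        (blocks >= 0)[:, None],
        math.sqrt(rho) * factors[np.clip(blocks, 0, None)]
        + math.sqrt(1.0 - rho) * noise,
        noise,
    )
    u = np.clip(stats.norm.cdf(z), 1e-12, 1.0 - 1e-12)
    r = config.dispersion  # NB size parameter; var = mu + mu^2 / r
    p = r / (r + mu)
    counts = stats.nbinom.ppf(u, r, p).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=symbols, columns=samples)
    lib = counts_df.sum(axis=0)
    lib[lib <= 0] = 1  # guard pathological tiny configs
    fpkm_df = counts_df.mul(1e9).div(lib, axis=1).div(lengths, axis=0)
    return ExpressionMatrix(
        counts=counts_df, fpkm=fpkm_df, groups=groups, gene_lengths=lengths
    )


def simulate_seed_sets(
    config: SimulationConfig, deg_list: GeneSet
) -> dict[str, GeneSet]:
    """Seed sets whose DEG-membership odds equal ``planted_enrichment_odds``.

    The number of DEG members is drawn from Fisher's noncentral
    hypergeometric at the configured odds (odds=inf forces the set
    inside the DEG list), then members are sampled uniformly from each
    stratum.
    """
    universe = gene_symbols(config.n_genes)
    deg = sorted(set(deg_list.genes) & set(universe))
    if set(deg_list.genes) - set(universe):
        raise ValueError("deg_list contains genes outside the simulated universe")
    non_deg = sorted(set(universe) - set(deg))
    out: dict[str, GeneSet] = {}
    for idx, (name, size) in enumerate(sorted(config.seed_set_sizes.items())):
        if size > config.n_genes:
            raise ValueError(f"seed set {name!r} larger than the universe")
        rng = _rng(config.rng_seed, "seed_sets", sub=idx)
        odds = config.planted_enrichment_odds
        if math.isinf(odds):
            if size > len(deg):
                raise ValueError(f"seed set {name!r}: odds=inf needs size <= n_deg")
            n_hits = size
        elif not deg or not non_deg:
            n_hits = size if not non_deg else 0
        else:
            n_hits = int(
                stats.nchypergeom_fisher.rvs(
                    len(universe), len(deg), size, odds, random_state=rng
                )
            )
        hits = rng.choice(deg, size=n_hits, replace=False) if n_hits else []
        rest = (
            rng.choice(non_deg, size=size - n_hits, replace=False)
            if size - n_hits
            else []
        )
        out[name] = GeneSet(name=name, genes=frozenset(hits) | frozenset(rest))
    return out


def simulate_pathways(
    config: SimulationConfig, seed_sets: dict[str, GeneSet]
) -> list[GmtRecord]:
    """GMT records with planted over-represented pathways.

    Planted pathways cycle over the seed sets and oversample seed genes
    until the one-sided hypergeometric tail (population = gene
    universe) drops below 1e-6 with at least ten seed hits; background
    pathways sample the universe uniformly.
    """
    universe = gene_symbols(config.n_genes)
    rng = _rng(config.rng_seed, "pathways")
    lo, hi = config.pathway_size_range
    names = sorted(seed_sets)
    records: list[GmtRecord] = []
    width = max(3, len(str(config.n_pathways)))
    for i in range(config.n_pathways):
        pid = f"PW{i + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        if i < config.planted_enriched_pathways and names:
            target = seed_sets[names[i % len(names)]]
            seed_pool = sorted(set(target.genes) & set(universe))
            other_pool = sorted(set(universe) - set(seed_pool))
            n_hits = _planted_hits(
                size, len(universe), len(seed_pool), min_hits=10
            )
            if n_hits > min(size, len(seed_pool)):
                raise ValueError(
                    f"cannot plant enrichment for {target.name!r}: "
                    "pathway_size_range/seed sizes infeasible"
                )
            members = set(rng.choice(seed_pool, size=n_hits, replace=False))
            members |= set(rng.choice(other_pool, size=size - n_hits, replace=False))
            desc = f"planted:{target.name}"
        else:
            members = set(rng.choice(universe, size=size, replace=False))
            desc = "background"
        records.append(
            GmtRecord(pathway_id=pid, description=desc, members=frozenset(members))
        )
    return records


def _planted_hits(size: int, N: int, n_seed: int, min_hits: int) -> int:
    """Seed-hit count giving hypergeometric tail well below 1e-6.

    Targets 1e-9 plus a two-hit margin so the pathway stays past the
    1e-6 keep threshold even when the downstream enrichment universe
    (genes with >=1 annotation) is somewhat smaller than the full
    simulated universe.
    """
    cap = min(size, n_seed)
    for x in range(min_hits, cap + 1):
        if stats.hypergeom.sf(x - 1, N, size, n_seed) < 1e-9:
            return min(x + 2, cap)
    return cap + 1  # infeasible sentinel; caller raises
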
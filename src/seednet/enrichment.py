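"""Seed-fraction statistics, bootstrap SEs and exact Fisher tests.

The fraction of a seed set within a gene universe is the unit statistic;
its uncertainty comes from bootstrapping the universe membership
indicator (default B=100 resamples), and nested universes are compared
with a two-tailed Fisher exact test on a disjoint 2x2 table (subset vs
complement) so overlapping groups are never double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from seednet.genesets import GeneSet


class FractionResult(NamedTuple):
    k: int
    N: int
    fraction: float


@dataclass
class EnrichmentResult:
    seed_set_name: str
    universe_name: str
    N: int
    k: int
    fraction: float
    bootstrap_se: float
    resamples: int
    comparison_partner: str | None = None
    fisher_p: float | None = None


def _as_genes(obj) -> frozenset[str]:
    return obj.genes if isinstance(obj, GeneSet) else frozenset(obj)


def seed_fraction(seed_set, universe) -> FractionResult:
    """(hits, universe size, fraction to 4 decimals) of seeds in a universe."""
    seeds = _as_genes(seed_set)
    uni = _as_genes(universe)
    if not uni:
        raise ValueError("empty universe")
    k = len(seeds & uni)
    N = len(uni)
    return FractionResult(k=k, N=N, fraction=round(k / N, 4))


def bootstrap_se_from_counts(
    k: int, N: int, B: int = 100, rng_seed: int = 0
) -> float:
    """Bootstrap SE of the fraction k/N from counts alone.

    Resamples the length-N membership indicator with replacement B
    times and returns the sample standard deviation of the resampled
    fractions. Resampling N indicators with replacement is drawing the
    hit count from Binomial(N, k/N).
    """
    if not 0 <= k <= N or N < 1:
        raise ValueError(f"need 0 <= k <= N, N >= 1; got k={k}, N={N}")
    if B < 2:
        raise ValueError("need B >= 2 resamples")
    rng = np.random.default_rng(rng_seed)
    fractions = rng.binomial(N, k / N, size=B) / N
    return float(fractions.std(ddof=1))


def bootstrap_se(seed_set, universe, B: int = 100, rng_seed: int = 0) -> float:
    """Bootstrap SE of the seed fraction within a universe."""
    k, N, _ = seed_fraction(seed_set, universe)
    return bootstrap_se_from_counts(k, N, B=B, rng_seed=rng_seed)


def fisher_exact_two_tailed(table) -> float:
    """Exact two-tailed Fisher p for a 2x2 table.

    Two-tailed rule: sum of the probabilities of all margin-fixed
    tables whose point probability is <= that of the observed table.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def fisher_two_tailed(k1: int, N1: int, k2: int, N2: int, nested: bool = True) -> float:
    """Two-tailed Fisher test comparing fractions k1/N1 vs k2/N2.

    With ``nested=True`` group 2 is a subset of group 1 and the table
    is built disjointly: (k2, N2-k2) vs (k1-k2, (N1-N2)-(k1-k2)).
    With ``nested=False`` the groups are independent and the table is
    (k1, N1-k1) vs (k2, N2-k2).
    """
    for k, N, tag in ((k1, N1, "1"), (k2, N2, "2")):
        if not 0 <= k <= N:
            raise ValueError(f"group {tag}: need 0 <= k <= N, got k={k}, N={N}")
    if nested:
        rest_hits = k1 - k2
        rest_size = N1 - N2
        if rest_hits < 0 or rest_size < 0 or rest_hits > rest_size:
            raise ValueError(
                "inconsistent nested counts: group 2 must be a subset of group 1"
            )
        table = [[k2, N2 - k2], [rest_hits, rest_size - rest_hits]]
    else:
        table = [[k1, N1 - k1], [k2, N2 - k2]]
    return fisher_exact_two_tailed(table)


def enrichment_panel(
    seed_sets: Sequence[GeneSet],
    universes: Sequence[GeneSet],
    B: int = 100,
    rng_seed: int = 0,
    nested: bool = True,
) -> pd.DataFrame:
    """Full cross of fractions, bootstrap SEs and consecutive Fisher p.

    ``universes`` is ordered from largest to smallest; with
    ``nested=True`` each universe after the first must be a subset of
    its predecessor, and the Fisher p on a row compares that universe
    with the previous one.
    """
    universes = list(universes)
    if nested:
        for prev, cur in zip(universes, universes[1:]):
            if not _as_genes(cur) <= _as_genes(prev):
                raise ValueError(
                    f"universe {cur.name!r} is not nested in {prev.name!r}"
                )
    rows = []
    for s_idx, seeds in enumerate(seed_sets):
        prev: FractionResult | None = None
        prev_name: str | None = None
        for u_idx, universe in enumerate(universes):
            k, N, frac = seed_fraction(seeds, universe)
            se = bootstrap_se_from_counts(
                k, N, B=B, rng_seed=hash((rng_seed, s_idx, u_idx)) % (2**32)
            )
            fisher_p = None
            if prev is not None:
                fisher_p = fisher_two_tailed(prev.k, prev.N, k, N, nested=nested)
            rows.append(
                EnrichmentResult(
                    seed_set_name=seeds.name,
                    universe_name=universe.name,
                    N=N,
                    k=k,
                    fraction=frac,
                    bootstrap_se=se,
                    resamples=B,
                    comparison_partner=prev_name,
                    fisher_p=fisher_p,
                )
            )
            prev = FractionResult(k, N, frac)
            prev_name = universe.name
    return pd.DataFrame([vars(r) for r in rows])
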
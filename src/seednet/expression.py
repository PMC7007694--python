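"""Expressed-gene filtering, FPKM derivation and co-expression edges.

The expressed-gene universe is defined by a hard count filter (strictly
more than ``min_count`` counts in at least ``min_samples`` samples).
Co-expression uses plain Pearson correlation on FPKM across all pooled
samples against a hard cutoff; by default the cutoff applies to |r|
(unsigned convention), with a ``signed`` mode and an optional
log2(FPKM+1) transform available as flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from seednet.genesets import GeneSet

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def _ordered(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


class ExpressionMatrix:
    """Genes-by-samples expression data with per-sample group labels.

    At least one of ``counts`` (non-negative integers) and ``fpkm``
    must be present; both are pandas DataFrames indexed by gene symbol
    with sample columns. ``gene_lengths`` (bp) enables FPKM derivation
    from counts.
    """

    def __init__(
        self,
        counts: pd.DataFrame | None = None,
        fpkm: pd.DataFrame | None = None,
        groups: Mapping[str, str] | None = None,
        gene_lengths: pd.Series | None = None,
    ):
        if counts is None and fpkm is None:
            raise ValueError("at least one of counts/fpkm is required")
        for df, label in ((counts, "counts"), (fpkm, "fpkm")):
            if df is not None:
                if df.index.has_duplicates:
                    raise ValueError(f"duplicate gene symbols in {label}")
                if (df.to_numpy() < 0).any():
                    raise ValueError(f"negative values in {label}")
        if counts is not None and fpkm is not None:
            if not counts.index.equals(fpkm.index) or not counts.columns.equals(
                fpkm.columns
            ):
                raise ValueError("counts and fpkm dimensions differ")
        self.counts = counts
        self.fpkm = fpkm
        ref = counts if counts is not None else fpkm
        self.groups = dict(groups or {})
        unknown = set(self.groups) - set(ref.columns)
        if unknown:
            raise ValueError(f"group labels for unknown samples: {sorted(unknown)}")
        if gene_lengths is not None:
            missing = set(ref.index) - set(gene_lengths.index)
            if missing:
                raise ValueError(f"gene_lengths missing {len(missing)} genes")
        self.gene_lengths = gene_lengths

    @property
    def genes(self) -> list[str]:
        ref = self.counts if self.counts is not None else self.fpkm
        return list(ref.index)

    @property
    def samples(self) -> list[str]:
        ref = self.counts if self.counts is not None else self.fpkm
        return list(ref.columns)

    def with_fpkm(self) -> "ExpressionMatrix":
        """Return self, deriving FPKM from counts if absent."""
        if self.fpkm is not None:
            return self
        if self.gene_lengths is None:
            raise ValueError("cannot derive FPKM without gene lengths")
        fpkm = compute_fpkm(self.counts, self.gene_lengths)
        return ExpressionMatrix(
            counts=self.counts,
            fpkm=fpkm,
            groups=self.groups,
            gene_lengths=self.gene_lengths,
        )


@dataclass
class CoexpressionEdgeSet:
    """Gene pairs passing the correlation cutoff, with their r values."""

    r_values: dict[Pair, float]
    cutoff: float = 0.75
    mode: str = "absolute"
    dropped_constant: frozenset[str] = field(default_factory=frozenset)

    @property
    def pairs(self) -> set[Pair]:
        return set(self.r_values)

    def __contains__(self, pair) -> bool:
        a, b = pair
        return _ordered(a, b) in self.r_values

    def __len__(self) -> int:
        return len(self.r_values)


def filter_expressed(
    matrix: ExpressionMatrix, min_count: int = 1, min_samples: int = 4
) -> GeneSet:
    """Expressed-gene universe: count > ``min_count`` in >= ``min_samples`` samples."""
    if matrix.counts is None:
        raise ValueError(
            "counts are required for the expressed filter; "
            "provide counts or an explicit universe gene list"
        )
    qualifying = (matrix.counts > min_count).sum(axis=1)
    kept = qualifying.index[qualifying >= min_samples]
    return GeneSet.from_symbols("expressed", kept, normalize=False)


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM = count * 1e9 / (library_size * gene_length_bp).

    ``library_sizes`` defaults to per-sample total counts.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:5].tolist()
        raise ValueError(f"missing gene lengths for {missing}")
    zero = lengths.index[lengths <= 0].tolist()
    if zero:
        raise ValueError(f"non-positive gene length for {zero[:5]}")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("non-positive library size")
    return counts.mul(1e9).div(library_sizes, axis=1).div(lengths, axis=0)


def coexpression_edges(
    matrix: ExpressionMatrix,
    cutoff: float = 0.75,
    mode: str = "absolute",
    genes=None,
    log_transform: bool = False,
) -> CoexpressionEdgeSet:
    """All-pairs Pearson co-expression edges at a hard cutoff.

    Correlation is computed on FPKM over all samples (groups pooled).
    ``mode="absolute"`` keeps pairs with |r| >= cutoff, ``"signed"``
    with r >= cutoff. Constant-profile genes have undefined r and form
    no edges; they are reported on the result and logged.
    """
    if mode not in ("absolute", "signed"):
        raise ValueError(f"unknown mode {mode!r}")
    matrix = matrix.with_fpkm()
    fpkm = matrix.fpkm
    if genes is not None:
        wanted = set(genes.genes if isinstance(genes, GeneSet) else genes)
        fpkm = fpkm.loc[[g for g in fpkm.index if g in wanted]]
    if fpkm.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    values = fpkm.to_numpy(dtype=float)
    if log_transform:
        values = np.log2(values + 1.0)
    stds = values.std(axis=1)
    constant = stds == 0
    if constant.any():
        logger.info(
            "excluding %d constant-profile genes from co-expression", constant.sum()
        )
    symbols = np.asarray(fpkm.index)
    keep_idx = np.flatnonzero(~constant)
    r_values: dict[Pair, float] = {}
    if keep_idx.size >= 2:
        corr = np.corrcoef(values[keep_idx])
        crit = np.abs(corr) if mode == "absolute" else corr
        iu, ju = np.triu_indices(len(keep_idx), k=1)
        hits = crit[iu, ju] >= cutoff
        for i, j in zip(iu[hits], ju[hits]):
            pair = _ordered(symbols[keep_idx[i]], symbols[keep_idx[j]])
            r_values[pair] = float(corr[i, j])
    return CoexpressionEdgeSet(
        r_values=r_values,
        cutoff=cutoff,
        mode=mode,
        dropped_constant=frozenset(symbols[constant]),
    )


def coexpression_table(edges: CoexpressionEdgeSet) -> pd.DataFrame:
    rows = [
        {"gene_a": a, "gene_b": b, "r": r}
        for (a, b), r in sorted(edges.r_values.items())
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])
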
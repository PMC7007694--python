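"""Gene symbols and named gene sets.

All joins in the pipeline are by gene symbol, so symbols are
case-normalized to the mouse convention (first letter upper, rest
lower) at every entry point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

REGULATION_LABELS = ("up", "down")


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol to mouse convention (``Grin1`` style).

    Whitespace is stripped; the first character is uppercased and the
    remainder lowercased. Empty input raises ``ValueError``.
    """
    s = symbol.strip()
    if not s:
        raise ValueError("empty gene symbol")
    return s[0].upper() + s[1:].lower()


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols with optional up/down regulation labels."""

    name: str
    genes: frozenset[str]
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: l for g, l in self.labels.items() if l not in REGULATION_LABELS}
        if bad:
            raise ValueError(f"invalid regulation labels: {bad}")
        stray = set(self.labels) - set(self.genes)
        if stray:
            raise ValueError(f"labels for genes not in set: {sorted(stray)}")

    @classmethod
    def from_symbols(
        cls,
        name: str,
        symbols,
        labels: Mapping[str, str] | None = None,
        normalize: bool = True,
    ) -> "GeneSet":
        if normalize:
            genes = frozenset(normalize_symbol(s) for s in symbols)
            labels = {normalize_symbol(g): l for g, l in (labels or {}).items()}
        else:
            genes = frozenset(symbols)
            labels = dict(labels or {})
        return cls(name=name, genes=genes, labels=labels)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.genes))

    def regulation(self, gene: str) -> str:
        """Regulation label for *gene*: ``up``, ``down`` or ``none``."""
        return self.labels.get(gene, "none")

    def intersection(self, other) -> frozenset[str]:
        other_genes = other.genes if isinstance(other, GeneSet) else frozenset(other)
        return self.genes & other_genes
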
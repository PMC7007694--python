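"""Readers and writers for every external file the pipeline touches.

Formats: TSV edge lists (BioGRID tab3 column names supported through a
``column_map``), plain-text gene lists with optional regulation labels,
Broad-dialect GMT pathway files, expression matrix TSVs (first column
gene symbol, remaining columns samples), and the network node/edge
tables written by the pipeline.

Parsing is deliberately dumb: duplicate edges and self-loops survive the
parser and are collapsed/dropped by network construction, which keeps
parsing pure and round-trip stable.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from seednet.genesets import GeneSet, normalize_symbol


class FormatError(ValueError):
    """Malformed input file."""


class EdgeRecord(NamedTuple):
    """One undirected interaction row as parsed (symbols normalized)."""

    gene_a: str
    gene_b: str
    source_tag: str = ""


@dataclass(frozen=True)
class GmtRecord:
    """One GMT line: pathway id, free-text description, member symbols."""

    pathway_id: str
    description: str
    members: frozenset[str]


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(
    path, column_map: Mapping[str, str] | None = None
) -> list[EdgeRecord]:
    """Parse a tab-separated edge list into :class:`EdgeRecord` rows.

    With ``column_map`` (mapping the roles ``gene_a``/``gene_b`` and
    optionally ``source_tag`` to header names) the first line is treated
    as a header and columns are located by name — this is how BioGRID
    tab3 files are read. Without it the file is read headerless, taking
    the first two columns as the gene pair.

    Duplicate rows and self-loops are preserved; deduplication is a
    network-construction concern.
    """
    path = Path(path)
    records: list[EdgeRecord] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [row for row in reader if row and any(f.strip() for f in row)]
    if not rows:
        warnings.warn(f"empty edge list: {path}")
        return records
    if column_map is None:
        idx_a, idx_b, idx_tag = 0, 1, None
        data_rows = rows
    else:
        header = [h.strip() for h in rows[0]]
        positions = {}
        for role in ("gene_a", "gene_b"):
            name = column_map.get(role)
            if name is None or name not in header:
                raise FormatError(f"mapped column for {role!r} not found: {name!r}")
            positions[role] = header.index(name)
        idx_a, idx_b = positions["gene_a"], positions["gene_b"]
        tag_name = column_map.get("source_tag")
        idx_tag = header.index(tag_name) if tag_name in header else None
        data_rows = rows[1:]
    for row in data_rows:
        if len(row) <= max(idx_a, idx_b):
            raise FormatError(f"short row in {path}: {row!r}")
        tag = row[idx_tag].strip() if idx_tag is not None and idx_tag < len(row) else ""
        records.append(
            EdgeRecord(
                gene_a=normalize_symbol(row[idx_a]),
                gene_b=normalize_symbol(row[idx_b]),
                source_tag=tag,
            )
        )
    return records


def write_edge_list(records: Iterable[EdgeRecord], path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for rec in records:
            writer.writerow([rec.gene_a, rec.gene_b, rec.source_tag])


# ---------------------------------------------------------------------------
# gene lists


def read_gene_list(path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list into a :class:`GeneSet`.

    An optional second tab-separated column carries a regulation label
    in {up, down}. Duplicate symbols collapse with a warning; the same
    gene listed with conflicting labels is an error.
    """
    path = Path(path)
    genes: set[str] = set()
    labels: dict[str, str] = {}
    conflicts: set[str] = set()
    dupes: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            gene = normalize_symbol(fields[0])
            if gene in genes:
                dupes.add(gene)
            genes.add(gene)
            if len(fields) > 1 and fields[1].strip():
                label = fields[1].strip().lower()
                if label not in ("up", "down"):
                    raise FormatError(
                        f"{path}:{lineno}: bad regulation label {label!r}"
                    )
                if gene in labels and labels[gene] != label:
                    conflicts.add(gene)
                labels[gene] = label
    if conflicts:
        raise FormatError(
            f"conflicting regulation labels in {path}: {sorted(conflicts)}"
        )
    if dupes:
        warnings.warn(f"duplicate symbols collapsed in {path}: {sorted(dupes)}")
    return GeneSet(name=name or path.stem, genes=frozenset(genes), labels=labels)


def write_gene_list(gene_set: GeneSet, path) -> None:
    with Path(path).open("w") as fh:
        for gene in sorted(gene_set.genes):
            label = gene_set.labels.get(gene)
            fh.write(f"{gene}\t{label}\n" if label else f"{gene}\n")


# ---------------------------------------------------------------------------
# GMT pathway annotations


def read_gmt(path) -> list[GmtRecord]:
    """Read a Broad-dialect GMT file (id TAB description TAB gene...)."""
    path = Path(path)
    records: list[GmtRecord] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            pathway_id = fields[0].strip()
            if pathway_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate pathway id {pathway_id!r}")
            seen.add(pathway_id)
            members = frozenset(
                normalize_symbol(g) for g in fields[2:] if g.strip()
            )
            if not members:
                raise FormatError(f"{path}:{lineno}: pathway with no members")
            records.append(
                GmtRecord(pathway_id=pathway_id, description=fields[1], members=members)
            )
    return records


def write_gmt(records: Iterable[GmtRecord], path) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(
                "\t".join([rec.pathway_id, rec.description, *sorted(rec.members)])
                + "\n"
            )


# ---------------------------------------------------------------------------
# networks

_SUPPORT_NAMES = {(True, False): "ppi", (True, True): "both", (False, True): "coexpr"}


def _support_name(ppi: bool, coexpr: bool) -> str:
    return _SUPPORT_NAMES[(bool(ppi), bool(coexpr))]


def write_network(network, edge_path, node_path=None) -> None:
    """Write a network's edge table (and optionally node table) as TSV.

    Edge columns: gene_a, gene_b, support (ppi|coexpr|both). Node
    columns: gene, role, regulation. Accepts an
    :class:`~seednet.interactome.InteractionNetwork` or a
    :class:`~seednet.subnetworks.Subnetwork`.
    """
    graph = network.graph
    with Path(edge_path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_a", "gene_b", "support"])
        for a, b, data in sorted(
            ((min(u, v), max(u, v), d) for u, v, d in graph.edges(data=True))
        ):
            writer.writerow(
                [a, b, _support_name(data.get("ppi", True), data.get("coexpr", False))]
            )
    if node_path is not None:
        roles = getattr(network, "roles", {})
        regulation = getattr(network, "regulation", {})
        with Path(node_path).open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["gene", "role", "regulation"])
            for node in sorted(graph.nodes):
                writer.writerow(
                    [node, roles.get(node, ""), regulation.get(node, "none")]
                )


def read_network_edges(edge_path) -> list[tuple[str, str, dict]]:
    """Read an edge TSV written by :func:`write_network`.

    Returns ``(gene_a, gene_b, {"ppi": bool, "coexpr": bool})`` tuples.
    """
    out: list[tuple[str, str, dict]] = []
    with Path(edge_path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "gene_a" not in reader.fieldnames:
            raise FormatError(f"missing edge-table header in {edge_path}")
        for row in reader:
            support = row.get("support", "ppi")
            out.append(
                (
                    row["gene_a"],
                    row["gene_b"],
                    {
                        "ppi": support in ("ppi", "both"),
                        "coexpr": support in ("coexpr", "both"),
                    },
                )
            )
    return out


def write_table(rows: Sequence[Mapping], path) -> None:
    """Write a list of homogeneous dict rows as a TSV with a header."""
    rows = list(rows)
    if not rows:
        Path(path).write_text("")
        return
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a genes-by-samples TSV (first column gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [normalize_symbol(g) for g in df.index]
    if df.index.has_duplicates:
        raise FormatError(f"duplicate gene symbols in {path}")
    return df


def write_matrix_tsv(df: pd.DataFrame, path, index_name: str = "gene") -> None:
    df = df.copy()
    df.index.name = index_name
    df.to_csv(path, sep="\t")


def read_sample_groups(path) -> dict[str, str]:
    """Read a two-column sample TSV (sample, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"sample table needs (sample, group) columns: {path}")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_sample_groups(groups: Mapping[str, str], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")
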
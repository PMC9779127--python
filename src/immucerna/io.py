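"""Readers, writers and domain containers for every table the pipeline touches.

The TSV dialect is fixed: tab delimiter, ``.`` decimal, no quoting, UTF-8.
Unicode minus signs (U+2212), as printed in journal tables, are normalized to
ASCII hyphens on read so published correlation tables can be ingested verbatim.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Scale = Literal["linear", "log2"]
Group = Literal["control", "case"]

GROUPS = ("control", "case")
BIOTYPES = ("mRNA", "lncRNA")

#: interaction labels used in SIF exports
SIF_LNC_EDGE = "lncRNA-miRNA"
SIF_MRNA_EDGE = "mRNA-miRNA"


def _read_text(path: str | Path) -> str:
    """Read a file as UTF-8 text with U+2212 normalized to ASCII hyphen."""
    return Path(path).read_text(encoding="utf-8").replace("−", "-")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression with two-group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per sample. All
        entries must be finite numbers.
    groups
        Mapping (or Series) sample id -> ``"control"`` / ``"case"`` covering
        exactly the samples in ``values``.
    scale
        ``"linear"`` for raw intensities/counts, ``"log2"`` for already
        log-transformed data.
    """

    values: pd.DataFrame
    groups: pd.Series | None
    scale: Scale = "log2"

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        self.values = v.astype(float)
        if self.groups is not None:
            if not isinstance(self.groups, pd.Series):
                self.groups = pd.Series(dict(self.groups), dtype=object)
            missing = [s for s in v.columns if s not in self.groups.index]
            if missing:
                raise ValueError(f"samples missing a group label: {missing}")
            unknown = [s for s in self.groups.index if s not in v.columns]
            if unknown:
                raise ValueError(f"group_map samples absent from the matrix: {unknown}")
            bad = set(self.groups) - set(GROUPS)
            if bad:
                raise ValueError(f"group labels must be in {GROUPS}, got {sorted(bad)}")
            self.groups = self.groups.reindex(v.columns)
            for g in GROUPS:
                n = int((self.groups == g).sum())
                if n < 2:
                    raise ValueError(f"need at least 2 samples per group; {g} has {n}")
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: Group) -> list[str]:
        if self.groups is None:
            raise ValueError("this expression matrix carries no group labels")
        return list(self.groups.index[self.groups == group])

    def log2_values(self) -> pd.DataFrame:
        """Expression on the log2 scale (log2(x+1) applied to linear input)."""
        if self.scale == "log2":
            return self.values
        return np.log2(self.values + 1.0)

    def linear_values(self) -> pd.DataFrame:
        """Expression on the linear scale (2**x - 1, clipped at 0, for log2 input)."""
        if self.scale == "linear":
            return self.values
        return (np.exp2(self.values) - 1.0).clip(lower=0.0)


def read_expression_table(
    path: str | Path,
    group_map: Mapping[str, str],
    scale: Scale = "log2",
    collapse: Literal["max", "mean"] = "max",
) -> ExpressionMatrix:
    """Read a tab-separated genes-by-samples matrix.

    First column holds gene symbols, the header row sample identifiers.
    Duplicate gene rows (multiple probes per symbol) are collapsed by the
    per-sample ``max`` (default) or ``mean``. Every header sample must be
    present in ``group_map`` and vice versa.
    """
    if collapse not in ("max", "mean"):
        raise ValueError(f"collapse must be 'max' or 'mean', got {collapse!r}")
    raw = pd.read_csv(
        _io.StringIO(_read_text(path)), sep="\t", index_col=0, dtype=str
    )
    missing = [s for s in raw.columns if s not in group_map]
    if missing:
        raise ValueError(f"samples absent from group_map: {missing}")
    num = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric value {raw.loc[gene, col]!r} at gene {gene!r}, "
                f"sample {col!r}"
            )
        num[col] = converted
    if num.index.has_duplicates:
        num = num.groupby(level=0, sort=False).max() if collapse == "max" \
            else num.groupby(level=0, sort=False).mean()
    num.index.name = None
    num.columns.name = None
    groups = pd.Series({s: group_map[s] for s in num.columns}, dtype=object)
    return ExpressionMatrix(values=num, groups=groups, scale=scale)


def write_expression_table(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_group_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, group) TSV into a group map."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(_read_text(path).splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 2 columns, got {len(parts)}")
        sample, group = (p.strip() for p in parts)
        if lineno == 1 and group not in GROUPS:
            continue  # header row
        if group not in GROUPS:
            raise ValueError(f"line {lineno}: group must be in {GROUPS}, got {group!r}")
        out[sample] = group
    return out


# ---------------------------------------------------------------------------
# Gene catalog
# ---------------------------------------------------------------------------


@dataclass
class GeneCatalog:
    """Per-gene biotype (mRNA / lncRNA) plus an immune-membership flag."""

    table: pd.DataFrame  # index gene_id, columns: biotype, is_immune

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate catalog genes: {dups}")
        bad = set(t["biotype"]) - set(BIOTYPES)
        if bad:
            raise ValueError(f"biotype must be in {BIOTYPES}, got {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def biotype(self, gene: str) -> str:
        return str(self.table.at[gene, "biotype"])

    def is_immune(self, gene: str) -> bool:
        return bool(self.table.at[gene, "is_immune"])

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index


def read_gene_tables(
    catalog_path: str | Path,
    immune_list_path: str | Path,
    uppercase: bool = False,
) -> GeneCatalog:
    """Build a :class:`GeneCatalog` from a (gene, biotype) table and an
    ImmPort-style immune list (one symbol per row).

    ``is_immune`` is true iff the symbol appears in the immune list. Matching
    is exact and case-sensitive unless ``uppercase`` normalization is on.
    Immune symbols absent from the catalog are ignored with a warning.
    """
    norm = (lambda s: s.upper()) if uppercase else (lambda s: s)
    rows: dict[str, str] = {}
    for lineno, line in enumerate(_read_text(catalog_path).splitlines(), start=1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected (gene, biotype) row")
        gene, biotype = norm(parts[0]), parts[1]
        if lineno == 1 and biotype not in BIOTYPES and biotype.lower() == "biotype":
            continue
        if biotype not in BIOTYPES:
            raise ValueError(
                f"line {lineno}: biotype must be in {BIOTYPES}, got {biotype!r}"
            )
        if gene in rows:
            raise ValueError(f"line {lineno}: duplicate catalog gene {gene!r}")
        rows[gene] = biotype
    immune = {
        norm(line.strip())
        for line in _read_text(immune_list_path).splitlines()
        if line.strip()
    }
    orphan = immune - set(rows)
    if orphan:
        logger.warning(
            "%d immune symbols absent from catalog (ignored): %s",
            len(orphan), sorted(orphan)[:10],
        )
    table = pd.DataFrame(
        {
            "biotype": pd.Series(rows, dtype=object),
            "is_immune": pd.Series({g: g in immune for g in rows}, dtype=bool),
        }
    )
    return GeneCatalog(table=table)


def write_gene_tables(
    catalog: GeneCatalog, catalog_path: str | Path, immune_list_path: str | Path
) -> None:
    with open(catalog_path, "w", encoding="utf-8") as fh:
        for gene, row in catalog.table.iterrows():
            fh.write(f"{gene}\t{row['biotype']}\n")
    with open(immune_list_path, "w", encoding="utf-8") as fh:
        for gene, row in catalog.table.iterrows():
            if row["is_immune"]:
                fh.write(f"{gene}\n")


# ---------------------------------------------------------------------------
# miRNA-gene interaction table
# ---------------------------------------------------------------------------


@dataclass
class InteractionTable:
    """Bipartite miRNA <-> gene edge set (miRcode-style)."""

    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "InteractionTable":
        return cls(edges=frozenset((str(m), str(g)) for m, g in pairs))

    def mirnas_of(self, gene: str) -> set[str]:
        return {m for m, g in self.edges if g == gene}

    def targets_of(self, mirna: str) -> set[str]:
        return {g for m, g in self.edges if m == mirna}

    def gene_index(self) -> dict[str, set[str]]:
        """gene -> set of miRNAs, for repeated shared-miRNA joins."""
        idx: dict[str, set[str]] = {}
        for m, g in self.edges:
            idx.setdefault(g, set()).add(m)
        return idx

    def __len__(self) -> int:
        return len(self.edges)


def read_interaction_table(path: str | Path) -> InteractionTable:
    """Read a two-column (miRNA, gene) TSV; duplicate rows are deduplicated."""
    edges: set[tuple[str, str]] = set()
    for lineno, line in enumerate(_read_text(path).splitlines(), start=1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) != 2 or not all(parts):
            raise ValueError(f"line {lineno}: expected (miRNA, gene) row, got {line!r}")
        edges.add((parts[0], parts[1]))
    logger.info("read %d interaction edges from %s", len(edges), path)
    return InteractionTable(edges=frozenset(edges))


def write_interaction_table(table: InteractionTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mirna, gene in sorted(table.edges):
            fh.write(f"{mirna}\t{gene}\n")


# ---------------------------------------------------------------------------
# ceRNA network container + Cytoscape exports
# ---------------------------------------------------------------------------


@dataclass
class CeRNANetwork:
    """Tripartite lncRNA / miRNA / mRNA network derived from admitted pairs.

    Edges link each admitted pair's lncRNA and mRNA to every miRNA they
    share, so every miRNA node bridges at least one lncRNA and one mRNA.
    """

    node_types: dict[str, str] = field(default_factory=dict)  # node -> lncRNA|mRNA|miRNA
    edges: set[tuple[str, str]] = field(default_factory=set)  # (lncRNA|mRNA, miRNA)

    def nodes_of_type(self, node_type: str) -> set[str]:
        return {n for n, t in self.node_types.items() if t == node_type}

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edges if node in e)

    def is_empty(self) -> bool:
        return not self.edges

    def validate(self) -> None:
        for mir in self.nodes_of_type("miRNA"):
            partners = {a for a, b in self.edges if b == mir}
            kinds = {self.node_types[p] for p in partners}
            if not {"lncRNA", "mRNA"} <= kinds:
                raise ValueError(
                    f"miRNA node {mir!r} must bridge a lncRNA and an mRNA"
                )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node, t in self.node_types.items():
            g.add_node(node, type=t)
        for a, b in self.edges:
            label = SIF_LNC_EDGE if self.node_types[a] == "lncRNA" else SIF_MRNA_EDGE
            g.add_edge(a, b, interaction=label)
        return g


def export_network(
    network: CeRNANetwork, path: str | Path, format: Literal["SIF", "GraphML"] = "SIF"
) -> None:
    """Write a network in a Cytoscape-consumable format.

    SIF rows are ``source<TAB>interaction<TAB>target`` with interaction labels
    ``lncRNA-miRNA`` / ``mRNA-miRNA``; GraphML carries a ``type`` node
    attribute. Re-reading either export reconstructs the same edge set.
    """
    if network.is_empty():
        logger.warning("exporting empty ceRNA network to %s", path)
    if format == "SIF":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b in sorted(network.edges):
                label = (
                    SIF_LNC_EDGE
                    if network.node_types[a] == "lncRNA"
                    else SIF_MRNA_EDGE
                )
                fh.write(f"{a}\t{label}\t{b}\n")
    elif format == "GraphML":
        nx.write_graphml(network.to_networkx(), path)
    else:
        raise ValueError(f"unknown format {format!r}; use 'SIF' or 'GraphML'")


def read_network(path: str | Path, format: Literal["SIF", "GraphML"] = "SIF") -> CeRNANetwork:
    """Parse a network export back into a :class:`CeRNANetwork`."""
    net = CeRNANetwork()
    if format == "SIF":
        for lineno, line in enumerate(_read_text(path).splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 3 SIF columns")
            src, label, dst = parts
            src_type = "lncRNA" if label == SIF_LNC_EDGE else "mRNA"
            net.node_types[src] = src_type
            net.node_types[dst] = "miRNA"
            net.edges.add((src, dst))
    elif format == "GraphML":
        g = nx.read_graphml(path)
        for node, data in g.nodes(data=True):
            net.node_types[str(node)] = data["type"]
        for a, b in g.edges():
            a, b = str(a), str(b)
            if net.node_types[a] == "miRNA":
                a, b = b, a
            net.edges.add((a, b))
    else:
        raise ValueError(f"unknown format {format!r}")
    return net
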
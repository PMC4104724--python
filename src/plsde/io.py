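"""Readers and writers for every external representation the pipeline touches.

In-memory containers
--------------------
expression matrix
    :class:`pandas.DataFrame`, probes as rows (GEO series-matrix convention),
    samples as columns, values on the log2 scale. Transposed to the
    samples x features orientation only at the modelling boundary.
phenotype
    :class:`pandas.Series` of ``int`` labels in {0, 1} (0 = control,
    1 = case), indexed by sample id and ordered like the expression columns.
probe annotation
    :class:`pandas.Series` mapping probe id -> gene symbol (upper-cased;
    empty string = unannotated probe).
gene sets
    :class:`GeneSetCollection` of :class:`GeneSet` records (GMT on disk).
interaction network
    :class:`networkx.Graph` with gene-symbol nodes (SIF or GraphML on disk).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import FormatError, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_phenotype",
    "write_phenotype",
    "read_annotation",
    "write_annotation",
    "read_gene_sets",
    "write_gene_sets",
    "read_edge_list",
    "write_network",
]


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named gene set: unique upper-case member symbols, insertion order kept."""

    set_id: str
    description: str
    members: tuple[str, ...]
    namespace: str = "pathway"

    @property
    def size(self) -> int:
        return len(self.members)

    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass
class GeneSetCollection:
    """An ordered collection of :class:`GeneSet` with unique ids."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate gene-set id(s): {', '.join(dup)}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    @property
    def ids(self) -> list[str]:
        return [s.set_id for s in self.sets]

    def namespaces(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sets:
            seen.setdefault(s.namespace)
        return list(seen)

    def universe(self, namespace: str | None = None) -> frozenset[str]:
        """Union of member symbols, optionally restricted to one namespace."""
        out: set[str] = set()
        for s in self.sets:
            if namespace is None or s.namespace == namespace:
                out.update(s.members)
        return frozenset(out)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, *, impute: bool = False) -> pd.DataFrame:
    """Read a tab-delimited probes x samples log2 expression matrix.

    First column holds probe ids, the header row holds sample ids. With
    ``impute=True`` missing cells are filled with the probe's row mean;
    otherwise any missing or non-numeric cell is a located error.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dup = sorted(raw.index[raw.index.duplicated()].unique())
        raise FormatError(f"{path}: duplicate probe id(s): {', '.join(map(str, dup))}")
    if raw.columns.has_duplicates:
        dup = sorted(raw.columns[raw.columns.duplicated()].unique())
        raise FormatError(f"{path}: duplicate sample id(s): {', '.join(map(str, dup))}")

    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at probe "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    if values.isna().to_numpy().any():
        if impute:
            values = values.apply(lambda row: row.fillna(row.mean()), axis=1)
            if values.isna().to_numpy().any():
                raise FormatError(f"{path}: probe with all values missing")
        else:
            r, c = np.argwhere(values.isna().to_numpy())[0]
            raise FormatError(
                f"{path}: missing value at probe {values.index[r]!r}, "
                f"sample {values.columns[c]!r} (pass impute=True to fill)"
            )
    if values.shape[0] < 2 or values.shape[1] < 4:
        raise FormatError(
            f"{path}: expression matrix must be at least 2 probes x 4 samples, "
            f"got {values.shape[0]} x {values.shape[1]}"
        )
    return values.astype(float)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------

def read_phenotype(path: str | Path, expr: pd.DataFrame) -> pd.Series:
    """Read a two-column (sample_id, label) table and align it to ``expr``.

    Labels are coerced to {0, 1}; both classes must be present; every
    expression sample must be covered. Extra samples in the file are
    dropped with a log message.
    """
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if tab.shape[1] != 2:
        raise FormatError(f"{path}: expected exactly 2 columns, got {tab.shape[1]}")
    tab.columns = ["sample_id", "label"]
    if tab["sample_id"].duplicated().any():
        dup = sorted(tab.loc[tab["sample_id"].duplicated(), "sample_id"].unique())
        raise FormatError(f"{path}: duplicate sample id(s): {', '.join(dup)}")
    labels = pd.to_numeric(tab["label"], errors="coerce")
    bad = labels.isna() | ~labels.isin([0, 1])
    if bad.any():
        row = tab.loc[bad].iloc[0]
        raise FormatError(
            f"{path}: label {row['label']!r} for sample {row['sample_id']!r} "
            "is not in {0, 1}"
        )
    mapping = pd.Series(labels.astype(int).to_numpy(), index=tab["sample_id"].to_numpy())
    missing = [s for s in expr.columns if s not in mapping.index]
    if missing:
        raise FormatError(f"{path}: phenotype missing sample(s): {', '.join(map(str, missing))}")
    extra = mapping.index.difference(expr.columns)
    if len(extra):
        logger.info("phenotype file lists %d sample(s) absent from the expression matrix", len(extra))
    pheno = mapping.reindex(expr.columns).astype(int)
    pheno.name = "label"
    pheno.index.name = "sample_id"
    if pheno.nunique() < 2:
        raise FormatError(f"{path}: both classes (0 and 1) must be present")
    return pheno


def write_phenotype(pheno: pd.Series, path: str | Path) -> None:
    pheno.rename("label").to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> pd.Series:
    """Read a two-column (probe_id, gene symbol) table.

    Empty symbols are retained as ``""`` (unannotated probes); symbols are
    upper-cased so case conventions of different sources agree.
    """
    tab = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if tab.shape[1] != 2:
        raise FormatError(f"{path}: expected exactly 2 columns, got {tab.shape[1]}")
    tab.columns = ["probe_id", "symbol"]
    if tab["probe_id"].duplicated().any():
        dup = sorted(tab.loc[tab["probe_id"].duplicated(), "probe_id"].unique())
        raise FormatError(f"{path}: duplicate probe row(s): {', '.join(dup)}")
    ann = pd.Series(
        tab["symbol"].str.strip().str.upper().to_numpy(),
        index=tab["probe_id"].to_numpy(),
        name="symbol",
    )
    ann.index.name = "probe_id"
    return ann


def write_annotation(annotation: pd.Series, path: str | Path) -> None:
    annotation.rename("symbol").to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path, *, namespace: str = "pathway") -> GeneSetCollection:
    """Read a GMT file: ``set_id TAB description TAB member...`` per line.

    Duplicate members within a line are dropped (first occurrence kept);
    a line with fewer than three fields or a duplicate set id is an error.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >= 3")
            set_id, description = fields[0], fields[1]
            if set_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            seen.add(set_id)
            members: dict[str, None] = {}
            for m in fields[2:]:
                m = m.strip().upper()
                if m:
                    members.setdefault(m)
            sets.append(GeneSet(set_id, description, tuple(members), namespace))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# interaction network (SIF in, SIF/GraphML out)
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a SIF-style (``a TAB type TAB b...``) or two-column symbol-pair file.

    Self-loops are dropped (count logged) and duplicate edges collapsed;
    symbols are upper-cased.
    """
    graph = nx.Graph()
    n_loops = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip().upper() for f in line.split("\t") if f.strip()]
            if len(fields) == 1:
                graph.add_node(fields[0])
                continue
            if len(fields) == 2:
                source, partners = fields[0], fields[1:]
            else:
                source, partners = fields[0], fields[2:]  # SIF: skip interaction type
            graph.add_node(source)
            for partner in partners:
                if partner == source:
                    n_loops += 1
                    continue
                graph.add_edge(source, partner)
    if n_loops:
        logger.info("dropped %d self-loop(s) while reading %s", n_loops, path)
    return graph


def write_network(graph: nx.Graph, path: str | Path, dialect: str = "sif") -> None:
    """Write a network in a Cytoscape-loadable dialect (``sif`` or ``graphml``).

    Nodes and edges are emitted in sorted order so identical graphs always
    produce identical bytes.
    """
    if dialect not in ("sif", "graphml"):
        raise InvalidParameterError(f"unknown network dialect {dialect!r}")
    ordered = nx.Graph()
    for node in sorted(graph.nodes):
        ordered.add_node(node, **graph.nodes[node])
    for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
        ordered.add_edge(u, v, **graph.edges[u, v])
    if dialect == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            isolated = [n for n in ordered.nodes if ordered.degree(n) == 0]
            for u, v in ordered.edges:
                fh.write(f"{u}\tpp\t{v}\n")
            for node in isolated:
                fh.write(f"{node}\n")
    else:
        nx.write_graphml(ordered, path, named_key_ids=True, edge_id_from_attribute=None)


def read_network(path: str | Path, dialect: str = "sif") -> nx.Graph:
    """Inverse of :func:`write_network` (used for round-trip validation)."""
    if dialect == "sif":
        return read_edge_list(path)
    if dialect == "graphml":
        return nx.read_graphml(path)
    raise InvalidParameterError(f"unknown network dialect {dialect!r}")


def validate_graph(graph: nx.Graph) -> None:
    """Assert the simple-graph invariant: no self-loops, degree sum = 2|E|."""
    if any(u == v for u, v in graph.edges):
        raise FormatError("graph contains self-loops")
    if sum(d for _, d in graph.degree()) != 2 * graph.number_of_edges():
        raise FormatError("degree sum does not equal twice the edge count")
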
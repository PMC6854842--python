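"""Heterogeneous molecular association network (MAN) construction.

The MAN is an undirected network whose nodes are molecules or medical
entities of five types (lncRNA, miRNA, protein, drug, disease) and whose
edges fall into nine association categories, one per legal unordered type
pair.  Identifiers are assumed pre-unified (one namespace per type); the
builder only strips whitespace and treats ids case-sensitively.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "MoleculeType",
    "AssociationCategory",
    "Node",
    "Association",
    "MANGraph",
    "EdgeListParseError",
    "load_edge_list",
    "build_man",
    "adjacency_matrix",
    "summarize",
    "write_graph_tsv",
    "read_graph_tsv",
]


class MoleculeType(str, Enum):
    LNCRNA = "lncRNA"
    MIRNA = "miRNA"
    PROTEIN = "protein"
    DRUG = "drug"
    DISEASE = "disease"


class AssociationCategory(str, Enum):
    """The nine legal association categories of the MAN."""

    MIRNA_LNCRNA = "miRNA-lncRNA"
    MIRNA_DISEASE = "miRNA-disease"
    MIRNA_PROTEIN = "miRNA-protein"
    LNCRNA_PROTEIN = "lncRNA-protein"
    PROTEIN_DISEASE = "protein-disease"
    PROTEIN_PROTEIN = "protein-protein"
    LNCRNA_DISEASE = "lncRNA-disease"
    DRUG_DISEASE = "drug-disease"
    DRUG_PROTEIN = "drug-protein"

    @property
    def type_pair(self) -> tuple[MoleculeType, MoleculeType]:
        a, b = self.value.split("-")
        return MoleculeType(a), MoleculeType(b)


_PAIR_TO_CATEGORY: dict[frozenset[MoleculeType], AssociationCategory] = {
    frozenset(c.type_pair): c for c in AssociationCategory
}


def category_for_types(
    type_a: MoleculeType, type_b: MoleculeType
) -> AssociationCategory:
    """Map an unordered molecule-type pair to its association category.

    Raises ``ValueError`` for the pairs that are not part of the network
    (e.g. miRNA-drug, disease-disease).
    """
    key = frozenset((type_a, type_b))
    try:
        return _PAIR_TO_CATEGORY[key]
    except KeyError:
        legal = ", ".join(c.value for c in AssociationCategory)
        raise ValueError(
            f"no association category for types ({type_a.value}, {type_b.value}); "
            f"legal categories are: {legal}"
        ) from None


@dataclass(frozen=True, order=True)
class Node:
    """A molecule in the network, sorted by (type, id)."""

    type: MoleculeType
    id: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("node id must be non-empty")


@dataclass(frozen=True)
class Association:
    source: Node
    target: Node
    category: AssociationCategory

    def __post_init__(self) -> None:
        expected = frozenset(self.category.type_pair)
        got = frozenset((self.source.type, self.target.type))
        if got != expected:
            raise ValueError(
                f"edge ({self.source.id}:{self.source.type.value}, "
                f"{self.target.id}:{self.target.type.value}) inconsistent with "
                f"category {self.category.value}"
            )
        if self.source == self.target and self.category is not AssociationCategory.PROTEIN_PROTEIN:
            raise ValueError(
                f"self-association {self.source.id} only permitted for protein-protein"
            )

    def canonical(self) -> tuple[Node, Node]:
        """Endpoints in deterministic (type, id) order."""
        return tuple(sorted((self.source, self.target)))  # type: ignore[return-value]


class EdgeListParseError(ValueError):
    pass


class MANGraph:
    """Undirected heterogeneous association network.

    Nodes are ordered deterministically by (type, id); ``index`` maps a
    node id to its position in that order. Duplicate undirected edges are
    collapsed and every retained node has degree >= 1 (after construction
    through :func:`build_man`).
    """

    def __init__(self, nodes: Iterable[Node], edges: Iterable[Association]):
        self.nodes: list[Node] = sorted(set(nodes))
        self._edge_map: dict[tuple[Node, Node], AssociationCategory] = {}
        for assoc in edges:
            self._edge_map.setdefault(assoc.canonical(), assoc.category)
        self.index: dict[str, int] = {n.id: i for i, n in enumerate(self.nodes)}
        if len(self.index) != len(self.nodes):
            dupes = len(self.nodes) - len(self.index)
            raise ValueError(f"{dupes} duplicate node id(s) across molecule types")

    @property
    def edges(self) -> list[Association]:
        return [
            Association(a, b, cat) for (a, b), cat in sorted(self._edge_map.items())
        ]

    def edge_keys(self) -> set[tuple[Node, Node]]:
        return set(self._edge_map)

    def has_edge(self, a: Node, b: Node) -> bool:
        return tuple(sorted((a, b))) in self._edge_map

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edge_map)

    def nodes_of_type(self, mtype: MoleculeType) -> list[Node]:
        return [n for n in self.nodes if n.type is mtype]

    def subgraph_without(self, removed: Iterable[Association]) -> "MANGraph":
        """Copy of the graph with the given edges deleted (nodes retained).

        Used by leakage-free cross-validation: held-out edges are removed
        before embedding, but their endpoints stay in the node order so
        that test pairs remain addressable (possibly with zero degree).
        """
        drop = {a.canonical() for a in removed}
        g = MANGraph.__new__(MANGraph)
        g.nodes = list(self.nodes)
        g._edge_map = {k: v for k, v in self._edge_map.items() if k not in drop}
        g.index = dict(self.index)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MANGraph):
            return NotImplemented
        return self.nodes == other.nodes and self._edge_map == other._edge_map

    def __repr__(self) -> str:
        return f"MANGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def load_edge_list(path: str | Path, category: AssociationCategory) -> list[Association]:
    """Parse a two-column TSV edge list into associations of one category.

    Lines starting with ``#`` are headers and skipped; ids are stripped of
    surrounding whitespace; duplicates are retained verbatim (dedup happens
    in :func:`build_man`).
    """
    if not isinstance(category, AssociationCategory):
        raise ValueError(f"unknown association category: {category!r}")
    type_a, type_b = category.type_pair
    out: list[Association] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            fields = [f for f in fields[:2] if f]
            if len(fields) != 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 2 non-empty tab-separated fields, "
                    f"got {line.rstrip()!r}"
                )
            src, tgt = fields
            out.append(Association(Node(type_a, src), Node(type_b, tgt), category))
    return out


def build_man(associations: Iterable[Association]) -> MANGraph:
    """Deduplicate edges, drop fully isolated pairs, and build the network.

    A *fully isolated pair* is a connected component consisting of exactly
    one edge (both endpoints degree 1): such a pair contributes no network
    context and is removed.
    """
    edge_map: dict[tuple[Node, Node], AssociationCategory] = {}
    for assoc in associations:
        edge_map.setdefault(assoc.canonical(), assoc.category)

    g = nx.Graph()
    for a, b in edge_map:
        g.add_edge(a, b)
    keep: set[tuple[Node, Node]] = set()
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_nodes() == 2 and sub.number_of_edges() == 1:
            continue  # isolated pair
        for a, b in sub.edges():
            keep.add(tuple(sorted((a, b))))  # type: ignore[arg-type]

    kept = [Association(a, b, edge_map[(a, b)]) for a, b in keep]
    if not kept and edge_map:
        warnings.warn("all components were isolated pairs; graph is empty")
    nodes = {n for a in kept for n in (a.source, a.target)}
    return MANGraph(nodes, kept)


def adjacency_matrix(graph: MANGraph, sparse: bool = False) -> np.ndarray | sp.csr_matrix:
    """Symmetric 0/1 adjacency in node order (diagonal nonzero only for
    protein self-interactions)."""
    if graph.n_nodes == 0:
        raise ValueError("adjacency of an empty graph is undefined")
    n = graph.n_nodes
    rows, cols = [], []
    for a, b in graph.edge_keys():
        i, j = graph.index[a.id], graph.index[b.id]
        rows.append(i)
        cols.append(j)
        if i != j:
            rows.append(j)
            cols.append(i)
    A = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=float
    )
    return A if sparse else A.toarray()


def summarize(graph: MANGraph) -> dict:
    """Node counts per molecule type and edge counts per category."""
    node_counts = {t.value: 0 for t in MoleculeType}
    for n in graph.nodes:
        node_counts[n.type.value] += 1
    edge_counts = {c.value: 0 for c in AssociationCategory}
    for a in graph.edges:
        edge_counts[a.category.value] += 1
    return {
        "n_nodes": graph.n_nodes,
        "n_edges": graph.n_edges,
        "nodes_per_type": node_counts,
        "edges_per_category": edge_counts,
    }


def write_graph_tsv(graph: MANGraph, path: str | Path, summary_path: str | Path | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#source_id\tsource_type\ttarget_id\ttarget_type\tcategory\n")
        for a in graph.edges:
            s, t = a.canonical()
            fh.write(
                f"{s.id}\t{s.type.value}\t{t.id}\t{t.type.value}\t{a.category.value}\n"
            )
    if summary_path is not None:
        with open(summary_path, "w", encoding="utf-8") as fh:
            json.dump(summarize(graph), fh, indent=2)
            fh.write("\n")


def read_graph_tsv(path: str | Path) -> MANGraph:
    assocs: list[Association] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise EdgeListParseError(f"{path}:{lineno}: expected 5 fields")
            sid, stype, tid, ttype, cat = fields
            assocs.append(
                Association(
                    Node(MoleculeType(stype), sid),
                    Node(MoleculeType(ttype), tid),
                    AssociationCategory(cat),
                )
            )
    nodes = {n for a in assocs for n in (a.source, a.target)}
    return MANGraph(nodes, assocs)


def load_edge_dir(
    edge_dir: str | Path, mapping: Mapping[str, AssociationCategory] | None = None
) -> list[Association]:
    """Load every per-category edge list in a directory.

    By default each file ``<category>.tsv`` (e.g. ``miRNA-disease.tsv``) is
    read with its filename's category.
    """
    edge_dir = Path(edge_dir)
    out: list[Association] = []
    if mapping is None:
        mapping = {}
        for c in AssociationCategory:
            p = edge_dir / f"{c.value}.tsv"
            if p.exists():
                mapping[p.name] = c
        if not mapping:
            raise FileNotFoundError(f"no per-category edge lists found in {edge_dir}")
    for fname, category in mapping.items():
        out.extend(load_edge_list(edge_dir / fname, category))
    return out
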
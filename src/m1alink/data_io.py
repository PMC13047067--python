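"""Core entity types and readers/writers for the standard input formats.

The pipeline works over three entity classes — N1-methyladenosine (m1A)
modification sites, circular RNAs and diseases — connected by binary
association edge lists. Sites additionally carry a 65-nt sequence window
(32 nt of flanking context on each side of the modified adenosine) and
diseases live in a Disease Ontology DAG under is_a relations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from Bio import SeqIO

__all__ = [
    "EntityIndex",
    "BinaryAssociationMatrix",
    "SequenceWindow",
    "OntologyDAG",
    "read_edge_list",
    "write_edge_list",
    "read_fasta_windows",
    "read_ontology",
    "write_predictions",
    "read_similarity_csv",
    "write_similarity_csv",
]

WINDOW_LENGTH = 65
CENTER = WINDOW_LENGTH // 2  # 0-based position of the modified adenosine


@dataclass(frozen=True)
class EntityIndex:
    """Ordered, duplicate-free universe of entity identifiers of one kind."""

    ids: tuple
    kind: str = "entity"

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        if len(self.ids) == 0:
            raise ValueError("EntityIndex must contain at least one id")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if list(self.ids).count(i) > 1})
            raise ValueError(f"duplicate ids in EntityIndex: {dupes[:5]}")
        object.__setattr__(self, "_pos", {i: k for k, i in enumerate(self.ids)})

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def __contains__(self, item) -> bool:
        return item in self._pos

    def position(self, entity_id: str) -> int:
        try:
            return self._pos[entity_id]
        except KeyError:
            raise KeyError(f"unknown {self.kind} id: {entity_id!r}") from None


@dataclass
class BinaryAssociationMatrix:
    """0/1 incidence between two entity classes with ordered ID lists."""

    rows: EntityIndex
    cols: EntityIndex
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValueError(
                f"shape {self.values.shape} does not match indexes "
                f"({len(self.rows)}, {len(self.cols)})"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def shape(self):
        return self.values.shape

    def density(self) -> float:
        return float(self.values.mean())

    def edges(self) -> list:
        """Return the (row_id, col_id) pairs with a 1 entry."""
        ii, jj = np.nonzero(self.values)
        return [(self.rows.ids[i], self.cols.ids[j]) for i, j in zip(ii, jj)]


@dataclass(frozen=True)
class SequenceWindow:
    """A 65-nt RNA window centred on an m1A site (site at position 33, 1-based)."""

    site_id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if len(seq) != WINDOW_LENGTH:
            raise ValueError(
                f"window {self.site_id!r} has length {len(seq)}, expected {WINDOW_LENGTH}"
            )
        if seq[CENTER] != "A":
            warnings.warn(
                f"window {self.site_id!r} does not have A at the central position "
                f"(found {seq[CENTER]!r})",
                stacklevel=2,
            )


@dataclass
class OntologyDAG:
    """Disease Ontology subgraph: child→parent is_a edges plus a decay factor.

    ``decay`` is the per-edge semantic contribution factor used by the Wang
    similarity method (each step up the DAG multiplies a term's contribution
    by ``decay``); it must lie strictly in (0, 1).
    """

    nodes: frozenset
    parents: dict = field(repr=False)  # child id -> frozenset of parent ids
    decay: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.decay < 1.0:
            raise ValueError(f"decay must be in (0, 1), got {self.decay}")
        graph = nx.DiGraph()
        graph.add_nodes_from(self.nodes)
        for child, ps in self.parents.items():
            for p in ps:
                graph.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        self._graph = graph
        children: dict = {n: set() for n in graph.nodes}
        for child, ps in self.parents.items():
            for p in ps:
                children.setdefault(p, set()).add(child)
        self._children = children

    def parents_of(self, node: str) -> frozenset:
        return frozenset(self.parents.get(node, frozenset()))

    def children_of(self, node: str) -> frozenset:
        return frozenset(self._children.get(node, frozenset()))

    def ancestors(self, node: str) -> frozenset:
        """All strict ancestors of ``node`` (the node itself excluded)."""
        if node not in self.nodes:
            raise KeyError(f"unknown ontology node: {node!r}")
        return frozenset(nx.descendants(self._graph, node))


# ---------------------------------------------------------------------------
# Readers / writers


def _parse_tsv_pairs(path) -> list:
    """Parse a 2+-column TSV; '#' lines are comments; returns (lineno, fields)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            rows.append((lineno, fields))
    return rows


def read_edge_list(path, rows: EntityIndex | None = None,
                   cols: EntityIndex | None = None,
                   row_kind: str = "entity", col_kind: str = "entity",
                   ) -> BinaryAssociationMatrix:
    """Read a TSV edge list into a binary incidence matrix.

    Repeated edges collapse to a single 1. When ``rows`` or ``cols`` is None
    the corresponding index is built from the file in first-appearance order;
    against a fixed index, an unknown ID raises ``KeyError``.
    """
    parsed = _parse_tsv_pairs(path)
    edges = []
    for lineno, fields in parsed:
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ValueError(f"{path}:{lineno}: expected at least 2 tab-separated columns")
        edges.append((fields[0], fields[1]))

    if rows is None:
        seen: dict = {}
        for r, _ in edges:
            seen.setdefault(r, None)
        if not seen:
            raise ValueError(f"{path}: empty edge list and no row index supplied")
        rows = EntityIndex(tuple(seen), kind=row_kind)
    if cols is None:
        seen = {}
        for _, c in edges:
            seen.setdefault(c, None)
        if not seen:
            raise ValueError(f"{path}: empty edge list and no column index supplied")
        cols = EntityIndex(tuple(seen), kind=col_kind)

    values = np.zeros((len(rows), len(cols)), dtype=np.int8)
    for r, c in edges:
        values[rows.position(r), cols.position(c)] = 1
    return BinaryAssociationMatrix(rows=rows, cols=cols, values=values)


def write_edge_list(assoc: BinaryAssociationMatrix, path) -> None:
    """Write the 1-entries of an incidence matrix as a TSV edge list."""
    with open(path, "w") as fh:
        for r, c in assoc.edges():
            fh.write(f"{r}\t{c}\n")


def read_fasta_windows(path) -> list:
    """Read 65-nt site windows from FASTA; record IDs become site IDs.

    DNA-styled records are accepted (T is transliterated to U). A record whose
    length is not 65 raises; duplicate record IDs raise.
    """
    windows = []
    seen = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate FASTA record id: {record.id!r}")
        seen.add(record.id)
        windows.append(SequenceWindow(site_id=record.id, sequence=str(record.seq)))
    return windows


def _looks_like_obo(path) -> bool:
    if str(path).endswith(".obo"):
        return True
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return line.startswith("format-version") or line.startswith("[")
    return False


def read_ontology(path, decay: float = 0.5) -> OntologyDAG:
    """Read a disease DAG from an OBO file (is_a relations) or a child→parent TSV.

    TSV lines with a single column declare an isolated node. A cycle in the
    edge relation is an error.
    """
    parents: dict = {}
    nodes: set = set()
    if _looks_like_obo(path):
        graph = obonet.read_obo(str(path))
        nodes.update(graph.nodes)
        for child, parent, key in graph.edges(keys=True):
            if key == "is_a":
                parents.setdefault(child, set()).add(parent)
    else:
        for lineno, fields in _parse_tsv_pairs(path):
            if len(fields) == 1 or not fields[1]:
                nodes.add(fields[0])
                continue
            child, parent = fields[0], fields[1]
            nodes.update((child, parent))
            parents.setdefault(child, set()).add(parent)
    parents = {c: frozenset(ps) for c, ps in parents.items()}
    return OntologyDAG(nodes=frozenset(nodes), parents=parents, decay=decay)


def write_predictions(scores, path) -> None:
    """Write (m1a_id, disease_id, score) rows as CSV, best-scored first.

    Ties break lexicographically on (m1a_id, disease_id).
    """
    frame = pd.DataFrame(list(scores), columns=["m1a_id", "disease_id", "score"])
    frame = frame.sort_values(
        by=["score", "m1a_id", "disease_id"], ascending=[False, True, True],
        kind="mergesort",
    )
    frame.to_csv(path, index=False, float_format="%.8g")


def write_similarity_csv(index: EntityIndex, values: np.ndarray, path) -> None:
    """Write a labeled square matrix as CSV (round-trips bit-exactly)."""
    frame = pd.DataFrame(np.asarray(values, dtype=np.float64),
                         index=list(index.ids), columns=list(index.ids))
    # shortest unique decimal representation: reading back with the
    # round_trip parser reproduces every double bit-exactly
    frame.to_csv(path, float_format=lambda v: np.format_float_positional(v, unique=True))


def read_similarity_csv(path, kind: str = "entity"):
    """Read a labeled square matrix CSV; returns (EntityIndex, ndarray)."""
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return EntityIndex(tuple(frame.index), kind=kind), frame.to_numpy(dtype=np.float64)
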
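"""Similarity matrices over diseases and m1A sites, and their fusion.

Diseases get two complementary views: Wang-style semantic similarity over
the Disease Ontology DAG (shared-ancestor contributions with multiplicative
decay) and Jaccard similarity of their binary association profiles. m1A
sites get cosine similarity of one-hot encoded 65-nt sequence windows and,
likewise, Jaccard similarity of association profiles. Each pair of views is
fused by an elementwise average.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import WINDOW_LENGTH, BinaryAssociationMatrix, EntityIndex, OntologyDAG, SequenceWindow

__all__ = [
    "SimilarityMatrix",
    "semantic_contributions",
    "disease_semantic_similarity",
    "jaccard_similarity",
    "one_hot_encode",
    "sequence_cosine_similarity",
    "fuse_similarities",
]

#: one-hot channel order per position
BASE_ORDER = "AUGC"
ONE_HOT_DIM = WINDOW_LENGTH * len(BASE_ORDER)


@dataclass
class SimilarityMatrix:
    """Square symmetric matrix of pairwise similarities in [0, 1]."""

    index: EntityIndex
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.index)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix is not symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")
        np.clip(self.values, 0.0, 1.0, out=self.values)


def semantic_contributions(dag: OntologyDAG, disease: str) -> dict:
    """Semantic contribution of a disease's ancestors to the disease itself.

    The disease contributes 1 to itself; any ancestor t contributes
    ``max(decay * contribution(t'))`` over its children t' lying on a path
    down to the disease. With a constant decay this equals
    ``decay ** (shortest upward distance)``; the max-over-children recursion
    is evaluated explicitly so alternative path structures stay correct.
    """
    if disease not in dag.nodes:
        raise KeyError(f"unknown disease: {disease!r}")
    contributions = {disease: 1.0}
    # best-first relaxation: contributions only shrink going up, so the
    # first time a node is popped its value is final (decay < 1)
    heap = [(-1.0, disease)]
    done = set()
    while heap:
        neg_value, node = heapq.heappop(heap)
        if node in done:
            continue
        done.add(node)
        value = -neg_value
        for parent in dag.parents_of(node):
            candidate = dag.decay * value
            if candidate > contributions.get(parent, 0.0):
                contributions[parent] = candidate
                heapq.heappush(heap, (-candidate, parent))
    return contributions


def disease_semantic_similarity(dag: OntologyDAG, index: EntityIndex) -> SimilarityMatrix:
    """Pairwise Wang semantic similarity over the diseases in ``index``.

    For diseases i, j with contribution maps C_i, C_j over their ancestor
    sets (each set including the disease itself):

        SSD(i, j) = sum_{t in shared} (C_i[t] + C_j[t])
                    / (sum_t C_i[t] + sum_t C_j[t])

    Diseases absent from the ontology get 0 off-diagonal (with a warning)
    and 1 on the diagonal.
    """
    n = len(index)
    maps: list = []
    missing = []
    for d in index:
        if d in dag.nodes:
            maps.append(semantic_contributions(dag, d))
        else:
            maps.append(None)
            missing.append(d)
    if missing:
        warnings.warn(
            f"{len(missing)} disease(s) absent from the ontology get zero semantic "
            f"similarity: {missing[:5]}",
            stacklevel=2,
        )
    totals = [sum(m.values()) if m is not None else 0.0 for m in maps]
    values = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        if maps[i] is None:
            continue
        for j in range(i + 1, n):
            if maps[j] is None:
                continue
            shared = maps[i].keys() & maps[j].keys()
            if not shared:
                continue
            num = sum(maps[i][t] + maps[j][t] for t in shared)
            values[i, j] = values[j, i] = num / (totals[i] + totals[j])
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(index=index, values=values)


def jaccard_similarity(assoc: BinaryAssociationMatrix, axis: str = "rows") -> SimilarityMatrix:
    """Jaccard similarity of binary association profiles.

    ``axis='rows'`` compares row entities by their rows (the m1A convention);
    ``axis='cols'`` compares column entities by their columns (the disease
    convention). For binary vectors x, y this is
    x·y / (||x||_1 + ||y||_1 − x·y) = |intersection| / |union|.
    Pairs of all-zero profiles get 0 off-diagonal; the diagonal is 1.
    """
    if axis == "rows":
        index, profiles = assoc.rows, assoc.values.astype(np.float64)
    elif axis == "cols":
        index, profiles = assoc.cols, assoc.values.T.astype(np.float64)
    else:
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    inter = profiles @ profiles.T
    sizes = profiles.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0  # exact symmetry against fp noise
    return SimilarityMatrix(index=index, values=values)


def one_hot_encode(window: SequenceWindow) -> np.ndarray:
    """One-hot encode a 65-nt window: per position A→1000, U→0100, G→0010, C→0001.

    Ambiguous characters (e.g. N) encode as all-zero. The result has
    dimension 65 × 4 = 260.
    """
    vector = np.zeros(ONE_HOT_DIM, dtype=np.float64)
    for pos, base in enumerate(window.sequence):
        channel = BASE_ORDER.find(base)
        if channel >= 0:
            vector[pos * 4 + channel] = 1.0
    return vector


def sequence_cosine_similarity(windows: list) -> SimilarityMatrix:
    """Pairwise cosine similarity of one-hot encoded windows.

    For pure-ACGU windows the cosine equals (matching positions) / 65.
    Zero-norm vectors (all-ambiguous windows) get 0 off-diagonal, 1 diagonal.
    """
    if not windows:
        raise ValueError("at least one window is required")
    index = EntityIndex(tuple(w.site_id for w in windows), kind="m1a_site")
    encoded = np.stack([one_hot_encode(w) for w in windows])
    norms = np.linalg.norm(encoded, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    values = (encoded / safe[:, None]) @ (encoded / safe[:, None]).T
    values[norms == 0, :] = 0.0
    values[:, norms == 0] = 0.0
    np.fill_diagonal(values, 1.0)
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(index=index, values=values)


def fuse_similarities(a: SimilarityMatrix, b: SimilarityMatrix) -> SimilarityMatrix:
    """Elementwise average of two similarity views over the same index."""
    if a.index.ids != b.index.ids:
        raise ValueError("cannot fuse similarities over different indexes")
    return SimilarityMatrix(index=a.index, values=(a.values + b.values) / 2.0)
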
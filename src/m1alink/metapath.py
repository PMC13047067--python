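"""Meta-path count matrices and the fused, normalized propagation matrices.

In the ternary m1A–circRNA–disease network, a meta-path is a typed walk
pattern; its instance-count matrix is a product of incidence matrices:

    A_m1 = A_MC A_MCᵀ              (m1A — circRNA — m1A)
    A_m2 = A_MC A_CD A_CDᵀ A_MCᵀ   (m1A — circRNA — disease — circRNA — m1A)
    A_d1 = A_CDᵀ A_CD              (disease — circRNA — disease)
    A_d2 = A_CDᵀ A_MCᵀ A_MC A_CD   (disease — circRNA — m1A — circRNA — disease)

Counts are kept raw; fusion is a fixed-weight sum with the similarity
matrix, and normalization is the symmetric degree scaling D^{-1/2} M D^{-1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import BinaryAssociationMatrix, EntityIndex
from .similarity import SimilarityMatrix

__all__ = [
    "MetaPathMatrix",
    "FusionWeights",
    "NormalizedAdjacency",
    "metapath_mm_via_c",
    "metapath_mm_via_cd",
    "metapath_dd_via_c",
    "metapath_dd_via_cm",
    "fuse_adjacency",
    "symmetric_normalize",
]


@dataclass
class MetaPathMatrix:
    """Symmetric nonnegative-integer matrix of meta-path instance counts."""

    index: EntityIndex
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        n = len(self.index)
        if self.values.shape != (n, n):
            raise ValueError(f"meta-path matrix shape {self.values.shape} != ({n}, {n})")
        if (self.values < 0).any():
            raise ValueError("meta-path counts must be nonnegative")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("meta-path matrix must be symmetric")
        self.values = self.values.astype(np.int64)


@dataclass(frozen=True)
class FusionWeights:
    """Weights for (direct meta-path, two-hop meta-path, similarity)."""

    w1: float = 0.6
    w2: float = 0.3
    w3: float = 0.1

    def __post_init__(self):
        if min(self.w1, self.w2, self.w3) < 0:
            raise ValueError("fusion weights must be nonnegative")


@dataclass
class NormalizedAdjacency:
    """Degree-normalized propagation matrix; spectral radius ≤ 1."""

    values: np.ndarray
    index: EntityIndex | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValueError("normalized adjacency contains non-finite entries")

    @property
    def shape(self):
        return self.values.shape


def _check_circ_match(amc: BinaryAssociationMatrix, acd: BinaryAssociationMatrix):
    if amc.cols.ids != acd.rows.ids:
        raise ValueError("circRNA indexes of the two association matrices differ")


def metapath_mm_via_c(amc: BinaryAssociationMatrix) -> MetaPathMatrix:
    """m1A×m1A counts of shared circRNA neighbours: A_MC A_MCᵀ."""
    values = amc.values.astype(np.int64) @ amc.values.astype(np.int64).T
    return MetaPathMatrix(index=amc.rows, values=values)


def metapath_mm_via_cd(amc: BinaryAssociationMatrix,
                       acd: BinaryAssociationMatrix) -> MetaPathMatrix:
    """m1A×m1A counts of m1A→circRNA→disease→circRNA→m1A path instances."""
    _check_circ_match(amc, acd)
    mc = amc.values.astype(np.int64)
    cd = acd.values.astype(np.int64)
    inner = mc @ cd  # m1A × disease two-hop counts
    return MetaPathMatrix(index=amc.rows, values=inner @ inner.T)


def metapath_dd_via_c(acd: BinaryAssociationMatrix) -> MetaPathMatrix:
    """disease×disease counts of shared circRNA neighbours: A_CDᵀ A_CD."""
    values = acd.values.astype(np.int64).T @ acd.values.astype(np.int64)
    return MetaPathMatrix(index=acd.cols, values=values)


def metapath_dd_via_cm(amc: BinaryAssociationMatrix,
                       acd: BinaryAssociationMatrix) -> MetaPathMatrix:
    """disease×disease counts of disease→circRNA→m1A→circRNA→disease paths."""
    _check_circ_match(amc, acd)
    mc = amc.values.astype(np.int64)
    cd = acd.values.astype(np.int64)
    inner = mc @ cd
    return MetaPathMatrix(index=acd.cols, values=inner.T @ inner)


def fuse_adjacency(p1: MetaPathMatrix, p2: MetaPathMatrix,
                   sim: SimilarityMatrix,
                   weights: FusionWeights = FusionWeights()) -> np.ndarray:
    """Weighted sum w1·p1 + w2·p2 + w3·sim over a shared index."""
    if not (p1.index.ids == p2.index.ids == sim.index.ids):
        raise ValueError("fuse_adjacency requires identical indexes")
    return (weights.w1 * p1.values + weights.w2 * p2.values
            + weights.w3 * sim.values).astype(np.float64)


def symmetric_normalize(matrix: np.ndarray,
                        index: EntityIndex | None = None) -> NormalizedAdjacency:
    """Symmetric degree normalization D^{-1/2} M D^{-1/2}.

    Degrees are row sums. Zero-degree rows (and columns) map to all-zero;
    their D^{-1/2} entry is treated as 0 (pseudo-inverse convention).
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if (matrix < 0).any():
        raise ValueError("symmetric_normalize requires a nonnegative matrix")
    degrees = matrix.sum(axis=1)
    inv_sqrt = np.where(degrees > 0, 1.0 / np.sqrt(np.where(degrees > 0, degrees, 1.0)), 0.0)
    values = inv_sqrt[:, None] * matrix * inv_sqrt[None, :]
    return NormalizedAdjacency(values=values, index=index)
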
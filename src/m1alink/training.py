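"""Training protocol: negative sampling, composite loss, CV folds, metrics.

Known m1A–disease associations are the positives; an equal number of
unconnected pairs is drawn uniformly from the bipartite complement as
negatives (1:1). Five-fold cross-validation partitions the positives; each
fold trains the encoder–decoder full-batch with Adam on the composite loss

    L = 0.7 L_BCE + 0.3 L_Focal,   alpha = 0.25, gamma = 2

and scores the held-out pairs. By default the label-derived Jaccard
similarities (and hence the fused features and adjacencies) are rebuilt per
fold from training edges only, so the reported metrics are leakage-free;
``leaky_similarity=True`` reproduces the protocol variant that computes
them once from the complete association matrix.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_io import BinaryAssociationMatrix, OntologyDAG
from .metapath import (FusionWeights, metapath_dd_via_c, metapath_dd_via_cm,
                       metapath_mm_via_c, metapath_mm_via_cd,
                       fuse_adjacency, symmetric_normalize)
from .model import GCNLinkPredictor
from .similarity import (SimilarityMatrix, disease_semantic_similarity,
                         fuse_similarities, jaccard_similarity,
                         sequence_cosine_similarity)

__all__ = [
    "LossConfig",
    "TrainConfig",
    "FoldSplit",
    "MetricsReport",
    "HeteroDataset",
    "build_dataset",
    "derive_seed",
    "sample_negatives",
    "composite_loss",
    "make_folds",
    "train_fold",
    "evaluate",
    "cross_validate",
]


def derive_seed(master: int, *words) -> int:
    """Derive a stable sub-seed (< 2^31) from a master seed and context words.

    Uses SHA-256 of the textual context so the derivation is reproducible
    across processes and Python versions (unlike built-in ``hash``).
    """
    digest = hashlib.sha256(repr((int(master),) + tuple(words)).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass(frozen=True)
class LossConfig:
    """Composite-loss weights; defaults follow the reference configuration."""

    bce_weight: float = 0.7
    focal_weight: float = 0.3
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0

    def __post_init__(self):
        if self.bce_weight < 0 or self.focal_weight < 0 or self.focal_gamma < 0:
            raise ValueError("loss weights and gamma must be nonnegative")
        if not 0 < self.focal_alpha < 1:
            raise ValueError("focal_alpha must lie in (0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Everything the CV protocol needs besides the data."""

    n_folds: int = 5
    epochs: int = 300
    lr: float = 1e-3
    threshold: float = 0.5
    weights_m: FusionWeights = field(default_factory=FusionWeights)
    weights_d: FusionWeights = field(default_factory=FusionWeights)
    loss: LossConfig = field(default_factory=LossConfig)
    leaky_similarity: bool = False
    n_layers: int = 3
    hidden_dim: int = 256
    embed_dim: int = 128
    n_heads: int = 4
    mlp_hidden: tuple = (32, 64, 32)


@dataclass
class FoldSplit:
    """One CV fold: positive partition plus disjoint sampled negatives."""

    fold_id: int
    train_pos: list
    test_pos: list
    train_neg: list
    test_neg: list
    seed: int


@dataclass
class MetricsReport:
    """Confusion counts at a threshold plus ranking metrics."""

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    precision: float
    recall: float
    f1: float
    auc: float
    aupr: float
    threshold: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tp", "tn", "fp", "fn", "acc", "precision", "recall", "f1",
                 "auc", "aupr", "threshold")}


@dataclass
class HeteroDataset:
    """The full input bundle: three incidence matrices plus similarity views.

    ``ssm`` (sequence cosine) and ``ssd`` (ontology semantic) are
    label-independent and fixed; the label-derived Jaccard views are built
    per fold by the trainer.
    """

    amc: BinaryAssociationMatrix  # m1A × circRNA
    acd: BinaryAssociationMatrix  # circRNA × disease
    amd: BinaryAssociationMatrix  # m1A × disease (the labels)
    ssm: SimilarityMatrix
    ssd: SimilarityMatrix

    def __post_init__(self):
        if self.amc.rows.ids != self.amd.rows.ids:
            raise ValueError("m1A indexes of AMC and AMD differ")
        if self.acd.cols.ids != self.amd.cols.ids:
            raise ValueError("disease indexes of ACD and AMD differ")
        if self.amc.cols.ids != self.acd.rows.ids:
            raise ValueError("circRNA indexes of AMC and ACD differ")
        if self.ssm.index.ids != self.amd.rows.ids:
            raise ValueError("SSM index does not match the m1A index")
        if self.ssd.index.ids != self.amd.cols.ids:
            raise ValueError("SSD index does not match the disease index")
        # meta-path counts depend only on AMC/ACD, never on the labels
        self.am1 = metapath_mm_via_c(self.amc)
        self.am2 = metapath_mm_via_cd(self.amc, self.acd)
        self.ad1 = metapath_dd_via_c(self.acd)
        self.ad2 = metapath_dd_via_cm(self.amc, self.acd)

    @property
    def positives(self) -> list:
        ii, jj = np.nonzero(self.amd.values)
        return list(zip(ii.tolist(), jj.tolist()))


def build_dataset(amc: BinaryAssociationMatrix, acd: BinaryAssociationMatrix,
                  amd: BinaryAssociationMatrix, windows: list,
                  dag: OntologyDAG) -> HeteroDataset:
    """Assemble a dataset, computing the two label-independent similarities."""
    order = {w.site_id: w for w in windows}
    missing = [s for s in amd.rows.ids if s not in order]
    if missing:
        raise KeyError(f"missing sequence windows for m1A sites: {missing[:5]}")
    ssm = sequence_cosine_similarity([order[s] for s in amd.rows.ids])
    ssd = disease_semantic_similarity(dag, amd.cols)
    return HeteroDataset(amc=amc, acd=acd, amd=amd, ssm=ssm, ssd=ssd)


def sample_negatives(positives, n_rows: int, n_cols: int, n: int,
                     seed: int, exclude=()) -> list:
    """Draw ``n`` distinct non-positive pairs uniformly without replacement."""
    forbidden = {i * n_cols + j for i, j in positives}
    forbidden.update(i * n_cols + j for i, j in exclude)
    total = n_rows * n_cols
    pool = np.array(sorted(set(range(total)) - forbidden), dtype=np.int64)
    if n > len(pool):
        raise ValueError(f"cannot sample {n} negatives from {len(pool)} candidate pairs")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n, replace=False)
    return [(int(f) // n_cols, int(f) % n_cols) for f in chosen]


def composite_loss(probs, labels, cfg: LossConfig = LossConfig()) -> float:
    """0.7·BCE + 0.3·Focal over N pairs (closed-form numpy evaluation).

    BCE  = −mean( y log p + (1−y) log(1−p) )
    Focal = −mean( alpha (1−p)^gamma y log p
                   + (1−alpha) p^gamma (1−y) log(1−p) )
    """
    p = np.asarray(probs, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"probs/labels length mismatch: {p.shape} vs {y.shape}")
    if p.size == 0:
        raise ValueError("need at least one pair")
    if (p <= 0).any() or (p >= 1).any():
        raise ValueError("probabilities must lie strictly in (0, 1)")
    log_p, log_q = np.log(p), np.log1p(-p)
    bce = -np.mean(y * log_p + (1 - y) * log_q)
    focal = -np.mean(cfg.focal_alpha * (1 - p) ** cfg.focal_gamma * y * log_p
                     + (1 - cfg.focal_alpha) * p ** cfg.focal_gamma * (1 - y) * log_q)
    return float(cfg.bce_weight * bce + cfg.focal_weight * focal)


def make_folds(positives, k: int, n_rows: int, n_cols: int, seed: int) -> list:
    """Seeded shuffle + round-robin partition of positives into k folds.

    Per fold, |positives| distinct negatives are drawn and split so that
    test negatives match the test positives 1:1 and train negatives the
    train positives 1:1, with the two sets disjoint.
    """
    positives = [tuple(p) for p in positives]
    if len(positives) < k:
        raise ValueError(f"need at least {k} positives, got {len(positives)}")
    rng = np.random.default_rng(derive_seed(seed, "fold-shuffle"))
    order = rng.permutation(len(positives))
    shuffled = [positives[i] for i in order]
    folds = []
    for fold_id in range(1, k + 1):
        test_pos = shuffled[fold_id - 1::k]
        train_pos = [p for idx, p in enumerate(shuffled) if idx % k != fold_id - 1]
        fold_seed = derive_seed(seed, "fold", fold_id)
        negatives = sample_negatives(positives, n_rows, n_cols,
                                     len(test_pos) + len(train_pos), fold_seed)
        folds.append(FoldSplit(
            fold_id=fold_id, train_pos=train_pos, test_pos=test_pos,
            train_neg=negatives[len(test_pos):], test_neg=negatives[:len(test_pos)],
            seed=fold_seed))
    return folds


def _fold_graphs(fold: FoldSplit, data: HeteroDataset, cfg: TrainConfig):
    """Build the fused features and normalized adjacencies for one fold."""
    if cfg.leaky_similarity:
        amd_eff = data.amd
    else:
        values = data.amd.values.copy()
        for i, j in fold.test_pos:
            values[i, j] = 0
        amd_eff = BinaryAssociationMatrix(rows=data.amd.rows, cols=data.amd.cols,
                                          values=values)
    jjm = jaccard_similarity(amd_eff, axis="rows")
    jjd = jaccard_similarity(amd_eff, axis="cols")
    ddm = fuse_similarities(data.ssm, jjm)
    dds = fuse_similarities(data.ssd, jjd)
    m1 = fuse_adjacency(data.am1, data.am2, ddm, cfg.weights_m)
    m2 = fuse_adjacency(data.ad1, data.ad2, dds, cfg.weights_d)
    return (ddm.values, dds.values,
            symmetric_normalize(m1, index=data.amd.rows),
            symmetric_normalize(m2, index=data.amd.cols))


def train_fold(fold: FoldSplit, data: HeteroDataset, cfg: TrainConfig = TrainConfig()):
    """Train on one fold; returns (fitted estimator, test pairs, test scores)."""
    features_m, features_d, adj_m, adj_d = _fold_graphs(fold, data, cfg)
    train_pairs = np.array(fold.train_pos + fold.train_neg, dtype=np.intp)
    train_labels = np.concatenate([np.ones(len(fold.train_pos)),
                                   np.zeros(len(fold.train_neg))])
    estimator = GCNLinkPredictor(
        n_layers=cfg.n_layers, hidden_dim=cfg.hidden_dim, embed_dim=cfg.embed_dim,
        n_heads=cfg.n_heads, mlp_hidden=cfg.mlp_hidden, lr=cfg.lr, epochs=cfg.epochs,
        bce_weight=cfg.loss.bce_weight, focal_weight=cfg.loss.focal_weight,
        focal_alpha=cfg.loss.focal_alpha, focal_gamma=cfg.loss.focal_gamma,
        random_state=derive_seed(fold.seed, "init"))
    estimator.fit(train_pairs, train_labels, adj_m=adj_m, adj_d=adj_d,
                  features_m=features_m, features_d=features_d)
    test_pairs = np.array(fold.test_pos + fold.test_neg, dtype=np.intp)
    test_scores = estimator.predict_proba(test_pairs)[:, 1]
    return estimator, test_pairs, test_scores


def evaluate(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Confusion counts at ``threshold`` plus AUC (rank statistic) and AUPR
    (step-wise precision–recall integration, the average-precision convention).

    With a single-class label set the ranking metrics are undefined and
    reported as NaN with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores/labels length mismatch")
    predicted = scores >= threshold
    tp = int(np.sum(predicted & (labels == 1)))
    tn = int(np.sum(~predicted & (labels == 0)))
    fp = int(np.sum(predicted & (labels == 0)))
    fn = int(np.sum(~predicted & (labels == 1)))
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else float("nan")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    if len(set(labels.tolist())) < 2:
        warnings.warn("single-class labels: AUC/AUPR undefined (NaN)", stacklevel=2)
        auc = aupr = float("nan")
    else:
        auc = float(roc_auc_score(labels, scores))
        aupr = float(average_precision_score(labels, scores))
    return MetricsReport(tp=tp, tn=tn, fp=fp, fn=fn, acc=acc, precision=precision,
                         recall=recall, f1=f1, auc=auc, aupr=aupr, threshold=threshold)


@dataclass
class CVResult:
    """Per-fold metrics plus the aggregate mean ± sd."""

    folds: list
    mean: dict
    sd: dict
    fold_scores: list  # (fold_id, test_pairs, scores, labels) per fold

    def as_dict(self) -> dict:
        return {"folds": [f.as_dict() for f in self.folds],
                "mean": self.mean, "sd": self.sd}


def cross_validate(data: HeteroDataset, cfg: TrainConfig = TrainConfig(),
                   seed: int = 0) -> CVResult:
    """Run the full k-fold protocol and aggregate the per-fold metrics."""
    n_rows, n_cols = data.amd.shape
    folds = make_folds(data.positives, cfg.n_folds, n_rows, n_cols, seed)
    reports, fold_scores = [], []
    for fold in folds:
        _, test_pairs, scores = train_fold(fold, data, cfg)
        labels = np.concatenate([np.ones(len(fold.test_pos), dtype=int),
                                 np.zeros(len(fold.test_neg), dtype=int)])
        reports.append(evaluate(scores, labels, threshold=cfg.threshold))
        fold_scores.append((fold.fold_id, test_pairs, scores, labels))
    keys = ("acc", "precision", "recall", "f1", "auc", "aupr")
    mean = {k: float(np.mean([getattr(r, k) for r in reports])) for k in keys}
    sd = {k: float(np.std([getattr(r, k) for r in reports], ddof=1)) for k in keys}
    return CVResult(folds=reports, mean=mean, sd=sd, fold_scores=fold_scores)
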
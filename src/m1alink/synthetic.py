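"""Self-contained synthetic datasets with planted community structure.

The generator emulates the shape of the real inputs — a tripartite binary
m1A–circRNA–disease network, 65-nt sequence windows and a small rooted
disease DAG — with a planted low-rank block structure: every entity belongs
to one of ``n_blocks`` latent communities; edges appear with probability
``p_in`` within a community and ``p_out`` across, then each entry is flipped
with probability ``noise``. Windows of sites in the same block share an
implanted sequence motif, and diseases of a block sit under a common parent
in the ontology, so every similarity view carries the same planted signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import (WINDOW_LENGTH, CENTER, BinaryAssociationMatrix, EntityIndex,
                      OntologyDAG, SequenceWindow, write_edge_list)

__all__ = ["SyntheticSpec", "SyntheticData", "generate", "expected_signal",
           "write_dataset", "DEFAULT_SPEC"]

#: fixed offset at which the block motif is implanted (well clear of the
#: central adenosine at position 32)
MOTIF_OFFSET = 5

_BASES = np.array(list("AUGC"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; defaults are the canonical fixture conditions."""

    n_m1a: int = 200
    n_circ: int = 30
    n_disease: int = 20
    n_blocks: int = 3
    p_in: float = 0.9
    p_out: float = 0.05
    motif_len: int = 10
    noise: float = 0.05
    seed: int = 42

    def __post_init__(self):
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if self.n_blocks > min(self.n_m1a, self.n_circ, self.n_disease):
            raise ValueError("n_blocks exceeds the smallest entity universe")
        if self.n_blocks < 1:
            raise ValueError("need at least one block")
        if not 0.0 <= self.noise < 0.5:
            raise ValueError("noise must lie in [0, 0.5)")
        if not 0 <= self.motif_len <= CENTER - MOTIF_OFFSET:
            raise ValueError(f"motif_len must lie in [0, {CENTER - MOTIF_OFFSET}]")


#: the canonical committed fixture descriptor (regenerated, never stored)
DEFAULT_SPEC = SyntheticSpec()


@dataclass
class SyntheticData:
    """Generator output: the three incidence matrices, windows, DAG, truth."""

    amc: BinaryAssociationMatrix
    acd: BinaryAssociationMatrix
    amd: BinaryAssociationMatrix
    windows: list
    dag: OntologyDAG
    blocks: dict  # kind -> ndarray of block labels


def _block_labels(rng: np.random.Generator, n: int, n_blocks: int) -> np.ndarray:
    """Balanced assignment (round-robin) in a seeded random order."""
    labels = np.arange(n) % n_blocks
    rng.shuffle(labels)
    return labels


def _block_matrix(rng: np.random.Generator, rows: np.ndarray, cols: np.ndarray,
                  spec: SyntheticSpec) -> np.ndarray:
    same = rows[:, None] == cols[None, :]
    prob = np.where(same, spec.p_in, spec.p_out)
    edges = rng.random(prob.shape) < prob
    flips = rng.random(prob.shape) < spec.noise
    return (edges ^ flips).astype(np.int8)


def generate(spec: SyntheticSpec = DEFAULT_SPEC) -> SyntheticData:
    """Generate a dataset fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    blocks = {
        "m1a_site": _block_labels(rng, spec.n_m1a, spec.n_blocks),
        "circRNA": _block_labels(rng, spec.n_circ, spec.n_blocks),
        "disease": _block_labels(rng, spec.n_disease, spec.n_blocks),
    }
    m1a_ids = EntityIndex(tuple(f"m1a_{i:04d}" for i in range(spec.n_m1a)), "m1a_site")
    circ_ids = EntityIndex(tuple(f"circ_{i:03d}" for i in range(spec.n_circ)), "circRNA")
    dis_ids = EntityIndex(tuple(f"DOID:9{i:03d}" for i in range(spec.n_disease)), "disease")

    amc = BinaryAssociationMatrix(m1a_ids, circ_ids,
                                  _block_matrix(rng, blocks["m1a_site"], blocks["circRNA"], spec))
    acd = BinaryAssociationMatrix(circ_ids, dis_ids,
                                  _block_matrix(rng, blocks["circRNA"], blocks["disease"], spec))
    amd = BinaryAssociationMatrix(m1a_ids, dis_ids,
                                  _block_matrix(rng, blocks["m1a_site"], blocks["disease"], spec))

    motifs = ["".join(rng.choice(_BASES, size=spec.motif_len)) for _ in range(spec.n_blocks)]
    windows = []
    for i, site_id in enumerate(m1a_ids):
        seq = rng.choice(_BASES, size=WINDOW_LENGTH)
        motif = motifs[blocks["m1a_site"][i]]
        seq[MOTIF_OFFSET:MOTIF_OFFSET + spec.motif_len] = list(motif)
        seq[CENTER] = "A"
        windows.append(SequenceWindow(site_id=site_id, sequence="".join(seq)))

    # balanced ontology: root -> one internal node per block -> disease leaves
    root = "DOID:4"
    block_nodes = [f"DOID:block{b}" for b in range(spec.n_blocks)]
    parents = {node: frozenset({root}) for node in block_nodes}
    for j, disease in enumerate(dis_ids):
        parents[disease] = frozenset({block_nodes[blocks["disease"][j]]})
    dag = OntologyDAG(nodes=frozenset([root, *block_nodes, *dis_ids]), parents=parents)

    return SyntheticData(amc=amc, acd=acd, amd=amd, windows=windows, dag=dag,
                         blocks=blocks)


def _effective_prob(p: float, noise: float) -> float:
    """Edge probability after the XOR label flip."""
    return p * (1 - noise) + (1 - p) * noise


def expected_signal(spec: SyntheticSpec = DEFAULT_SPEC) -> dict:
    """Closed-form expected off-diagonal meta-path counts, by block relation.

    For i ≠ j the expectations of the four count matrices follow from
    products of Bernoulli means (with an exact correction for the repeated
    inner edge when the two circRNA legs of a 4-step path coincide). Block
    sizes are the balanced ones the generator uses, so these values serve as
    simulation oracles.
    """
    p_in = _effective_prob(spec.p_in, spec.noise)
    p_out = _effective_prob(spec.p_out, spec.noise)

    def sizes(n: int) -> np.ndarray:
        base = np.full(spec.n_blocks, n // spec.n_blocks)
        base[: n % spec.n_blocks] += 1
        return base

    n_c = sizes(spec.n_circ)
    n_d = sizes(spec.n_disease)
    n_m = sizes(spec.n_m1a)
    blocks = np.arange(spec.n_blocks)

    def pmat(b_rows: np.ndarray, b_cols: np.ndarray) -> np.ndarray:
        return np.where(b_rows[:, None] == b_cols[None, :], p_in, p_out)

    # block-level probability matrices; expand with block sizes as weights
    p_mc = pmat(blocks, blocks)          # block of site × block of circ
    p_cd = pmat(blocks, blocks)
    # E[A_m1(i,j)] for site blocks (a, b): sum over circ blocks g of n_c[g] p(a,g) p(b,g)
    am1 = (p_mc * n_c[None, :]) @ p_mc.T
    ad1 = (p_cd.T * n_c[None, :]) @ p_cd
    # 4-step paths: G = P_mc P_cd weighted by circ-block sizes
    g_md = (p_mc * n_c[None, :]) @ p_cd            # site block × disease block
    # independence term + repeated-circ correction
    s_c = ((p_cd * (1 - p_cd)) * n_d[None, :]).sum(axis=1)   # per circ block
    am2 = (g_md * n_d[None, :]) @ g_md.T + (p_mc * (n_c * s_c)[None, :]) @ p_mc.T
    t_c = ((p_mc * (1 - p_mc)) * n_m[:, None]).sum(axis=0)   # per circ block
    g_dm = (p_cd.T * n_c[None, :]) @ p_mc.T        # disease block × site block
    ad2 = (g_dm * n_m[None, :]) @ g_dm.T + (p_cd.T * (n_c * t_c)[None, :]) @ p_cd

    def summarize(block_mat: np.ndarray) -> dict:
        within = float(np.mean(np.diag(block_mat)))
        off = block_mat[~np.eye(spec.n_blocks, dtype=bool)]
        between = float(np.mean(off)) if off.size else float("nan")
        return {"within": within, "between": between}

    return {"am1": summarize(am1), "am2": summarize(am2),
            "ad1": summarize(ad1), "ad2": summarize(ad2),
            "edge_prob_within": p_in, "edge_prob_between": p_out}


def write_dataset(data: SyntheticData, outdir) -> dict:
    """Write the dataset in the exact formats the readers consume.

    Returns a dict of the written paths (TSV edge lists, FASTA, OBO).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "m1a_circ": outdir / "m1a_circ.tsv",
        "circ_disease": outdir / "circ_disease.tsv",
        "m1a_disease": outdir / "m1a_disease.tsv",
        "windows": outdir / "windows.fasta",
        "ontology": outdir / "ontology.obo",
    }
    write_edge_list(data.amc, paths["m1a_circ"])
    write_edge_list(data.acd, paths["circ_disease"])
    write_edge_list(data.amd, paths["m1a_disease"])
    with open(paths["windows"], "w") as fh:
        for w in data.windows:
            fh.write(f">{w.site_id}\n{w.sequence}\n")
    with open(paths["ontology"], "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for node in sorted(data.dag.nodes):
            fh.write(f"[Term]\nid: {node}\nname: {node}\n")
            for parent in sorted(data.dag.parents_of(node)):
                fh.write(f"is_a: {parent} ! {parent}\n")
            fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
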
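# Methods

## Problem and model

`m1alink` predicts associations between N1-methyladenosine (m1A) RNA
modification sites and diseases. Verified m1A–disease pairs are scarce, so
the method enriches both entity classes with indirect evidence routed
through circular RNAs (circRNAs), forming a ternary m1A–circRNA–disease
heterogeneous network, and learns a pair scorer end to end.

The pipeline has four stages.

**1. Similarity views.** Diseases get (a) Wang-style semantic similarity
over the Disease Ontology DAG and (b) Jaccard similarity of their binary
m1A-association profiles. For a disease d, every term t in its ancestor
closure (including d itself) contributes

    C_d(d) = 1,   C_d(t) = max { α · C_d(t') : t' ∈ children(t) on a path to d }

with decay α = 0.5, and

    SSD(i, j) = Σ_{t ∈ shared} (C_i(t) + C_j(t)) / (Σ_t C_i(t) + Σ_t C_j(t)).

The ancestor closure includes the disease itself, which makes
self-similarity exactly 1 and matches the convention of the standard
Wang-method implementations. m1A sites get (a) cosine similarity of
one-hot encoded 65-nt windows (32 nt flanking each side of the modified
adenosine; A/U/G/C per position, so 65 × 4 = 260 dimensions; for pure-ACGU
windows the cosine is exactly the fraction of matching positions) and
(b) Jaccard similarity of their disease-association profiles. Each pair of
views is fused by an elementwise average (DDM for sites, DDS for diseases).

**2. Meta-path counts.** With incidence matrices A_MC (m1A × circRNA) and
A_CD (circRNA × disease), the four meta-path instance-count matrices are

    A_m1 = A_MC A_MCᵀ              A_d1 = A_CDᵀ A_CD
    A_m2 = A_MC A_CD A_CDᵀ A_MCᵀ   A_d2 = A_CDᵀ A_MCᵀ A_MC A_CD

Counts are kept raw; the propagation matrices are fixed-weight fusions
M1 = 0.6·A_m1 + 0.3·A_m2 + 0.1·DDM (and the disease analogue with DDS),
then symmetrically normalized, D^{-1/2} M D^{-1/2} with D the diagonal
row-sum matrix. Zero-degree rows use the pseudo-inverse convention
(0^{-1/2} ≡ 0); with the default weights the similarity term has unit
diagonal, so degrees are positive and the fallback only matters in ablation
configurations. The weights are config-exposed; (0, 0, 1) reproduces the
similarity-only ablation from configuration alone.

**3. Encoder.** Each entity class has its own L-layer GCN over its
normalized adjacency, H^(l) = ReLU(M̃ H^(l-1) W^(l-1)), with L = 3, hidden
width 256 and embedding width 128, followed by multi-head scaled
dot-product self-attention over the graph's nodes (4 heads, d_k = 32,
heads concatenated and linearly mapped back to 128) and a learned residual
combination H_final = H_attention + H_GCN W_residual. Attention is applied
separately per graph — each graph's node set is the token set — and the
residual maps are not shared between entity classes.

**4. Decoder and loss.** A pair (i, j) is scored by concatenating the two
128-d embeddings and passing the 256-d vector through an MLP with hidden
widths (32, 64, 32), ReLU between hidden layers, and a final logistic
unit, p_ij = σ(w h + b) with σ(x) = 1/(1+e^{-x}). Training minimizes

    L = 0.7 · L_BCE + 0.3 · L_Focal,   α = 0.25, γ = 2

full-batch with Adam (lr 1e-3, 300 epochs) on the known positives plus an
equal number of uniformly sampled non-associated pairs.

## Evaluation protocol

Five-fold cross-validation partitions the positive pairs (seeded shuffle,
round-robin). Per fold, negatives are drawn 1:1 without replacement from
the bipartite complement, with train and test negatives disjoint. Metrics:
confusion counts at threshold 0.5, ACC/Precision/Recall/F1, AUC (the
Mann–Whitney rank statistic over the ROC, with FPR = FP/(FP+TN)), and AUPR
by step-wise precision–recall integration (the average-precision
convention — trapezoidal PR integration would give slightly different
values). Single-class test sets yield NaN ranking metrics with a warning.

**Leakage control.** The Jaccard similarities derive from the m1A–disease
label matrix itself. By default they (and everything downstream: DDM, DDS,
the fused adjacencies and the input features) are rebuilt per fold from
training edges only, so reported CV metrics are honest. The
`leaky_similarity` flag instead computes them once from the complete
matrix — the protocol-literal variant; published pipelines of this family
typically do this, and the flag exists to reproduce that behaviour
explicitly rather than silently.

## Numerical choices

- **Weight initialization** is Glorot-uniform from the run seed; biases
  start at zero. The run seed derives per-fold sampling, shuffling and
  initialization seeds through a SHA-256 based derivation, so any single
  fold is reproducible in isolation.
- **Feature standardization.** Encoder inputs (each node's fused
  similarity profile) are column z-scored inside the estimator
  (`standardize_features=True`). The raw profiles have a large constant
  component aligned with the top eigenvector of the dense normalized
  adjacency; three propagation layers then shrink between-node differences
  by roughly the cube of the spectral gap and full-batch training can sit
  at a constant-output saddle for hundreds of epochs. Removing the
  constant direction makes every fold train reliably. Alternative
  initializations (He, LeCun-normal, orthogonal, reduced-gain Glorot) were
  evaluated and did not fix this.
- **Degenerate inputs.** All-zero association profiles get Jaccard 0
  off-diagonal and 1 on the diagonal; ambiguous bases (N) one-hot encode
  as all-zero with a zero-norm cosine guard; diseases absent from the
  ontology get zero semantic similarity with a warning.
- **Probabilities** are clipped to [1e-7, 1 − 1e-7] inside the loss only;
  reported scores are raw sigmoid outputs.
- **Ties** in ranked prediction output break lexicographically on
  (m1a_id, disease_id) so files are byte-stable.
- **Case-study masking.** The mask-one-disease hold-out mode treats the
  masked column as *unknown*, not negative: it is excluded from negative
  sampling during training (otherwise, on small networks, a large fraction
  of the column would be trained as negatives and its recovery actively
  suppressed). Prediction must rebuild the graphs with the same mask the
  checkpoint was trained with; the `predict` command takes the same
  `--mask-disease` flag for this.

## Synthetic data

The generator emulates the *shape* of the real inputs with planted,
recoverable structure: every entity is assigned to one of `n_blocks`
communities (balanced round-robin assignment in seeded random order, so no
block is empty at small n); each bipartite matrix is Bernoulli(p_in)
within-community and Bernoulli(p_out) across, then every entry is flipped
with probability `noise`; windows share an implanted per-block motif
(offset 5, default length 10) on an otherwise uniform background with a
central A; the ontology is a balanced tree (root → one node per block →
disease leaves). `expected_signal` gives closed-form expected meta-path
counts (including the repeated-edge correction for 4-step paths) for use
as simulation oracles.

The canonical fixture is 200 m1A sites × 30 circRNAs × 20 diseases,
3 blocks, p_in = 0.9, p_out = 0.05, motif 10 nt, noise = 0.05, seed 42 —
always regenerated from these parameters, never stored on disk.

**What the fixture does not emulate.** Real association data is far
sparser and has heavy-tailed degree distributions; real site–circRNA
mappings are near-functional (a site lies on few circRNAs) while the
fixture's are dense; disease ontologies are deep and irregular rather than
a two-level tree. Passing tests demonstrate that the machinery is correct
and that planted community signal is recovered; they do not certify
performance on database-derived data.

**Information ceiling.** Because fixture edges are independent given the
block assignments, an optimal scorer can only output P(edge | block pair).
At the canonical parameters this caps test AUC at ≈ 0.87 for the
leakage-free protocol (P(edge|same block) = 0.86, P(edge|cross) = 0.095
after flip noise, positives ≈ 82% same-block, sampled negatives ≈ 7%).
Measured CV performance sits at this ceiling (mean AUC ≈ 0.88 in both
leakage modes), which is the expected behaviour of a correct
implementation on this generator, not a deficiency of training.

**Leakage interacts with the ablation.** Under the leakage-free protocol
the similarity-only ablation (fusion weights (0, 0, 1)) scores below the
default meta-path fusion, as expected. Under the protocol-literal mode the
direction *reverses* (measured ≈ 0.94 vs 0.88 mean AUC over five seeds):
the label-derived Jaccard similarities then contain the held-out edges,
and making them the entire propagation graph lets the model exploit that
leak past the honest ceiling. Ablation comparisons are therefore only
meaningful leakage-free, which is how the package runs them.

## Problem sizes used in checks

Oracle equivalence checks use 100 random 100×50 binary matrices (Jaccard),
50 random window pairs (cosine), ten 20×10×8 tripartite networks
(meta-path enumeration), 1,000 random probability/label pairs (loss) and
500 scored pairs (AUC). End-to-end checks run the canonical fixture's full
5-fold protocol; the acceptance script averages the meta-path ablation
over two protocol seeds to stay desk-scale.

## Known limitations

- The encoder is full-batch and dense; complexity is O(n² · width) per
  epoch, fine for thousands of nodes but not for genome-scale site sets.
- Negative sampling treats unobserved pairs as negatives; no
  positive-unlabelled correction is applied.
- Meta-paths are fixed to the four specified patterns; fusion weights are
  fixed constants, not learned.
- Attention is dense over all nodes of a graph and adds little on small
  graphs; it is kept for fidelity to the architecture.
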
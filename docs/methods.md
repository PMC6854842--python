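# Methods

## The association network

The Molecular Association Network (MAN) is an undirected graph over five
entity types — lncRNA, miRNA, protein, drug, disease — with nine legal
association categories, one per permitted unordered type pair. Type pairs
outside the nine (e.g. miRNA–drug, disease–disease) are rejected at
construction. Identifiers are assumed to be pre-unified, one namespace
per molecule type; the builder strips surrounding whitespace and treats
ids case-sensitively, and no cross-database identifier mapping is
attempted. Self-interactions are admitted only in the protein–protein
category, where curated interactome data genuinely contains them.

Construction deduplicates undirected edges (a reversed duplicate is the
same edge, since all nine association categories are symmetric relations)
and then removes every *fully isolated pair* — a connected component
consisting of exactly one edge. We read "isolated pair" as
single-edge-component rather than "any degree-1 node" because an isolated
pair contributes no network context from which a behavior embedding could
learn anything, whereas a degree-1 node attached to the giant component
does. All retained nodes therefore have degree ≥ 1, and node order is
deterministic (sorted by type, then id), which makes adjacency matrices
and embeddings byte-reproducible.

## Behavior features: high-order proximity embedding

For adjacency A, a proximity matrix S is written as S = M_g⁻¹ M_l with
both factors sparse:

| measure           | M_g       | M_l          |
|-------------------|-----------|--------------|
| Katz              | I − βA    | βA           |
| common neighbors  | I         | A²           |
| Adamic–Adar       | I         | A·D⁻¹·A      |
| rooted PageRank   | I − αP    | (1 − α)I     |

with D the degree diagonal and P = D⁻¹A. The Katz series converges iff
β·σ_max(A) < 1; the default is β = 0.5/σ_max(A), halfway to the
convergence radius. σ_max is computed with a fixed Lanczos start vector
so the derived β (and hence everything downstream) is deterministic.
Adamic–Adar here uses inverse-degree weighting (D⁻¹), the form that
admits the sparse two-factor decomposition; the inverse-log-degree
variant common in link-prediction scoring does not factor this way.

S is assembled densely via a sparse LU solve of M_g S = M_l (the graphs
this package targets at evaluation scale are well below the size where
that matters) and factorized by truncated SVD: Z_s = U_d Σ_d^{1/2},
Z_t = V_d Σ_d^{1/2}. By Eckart–Young, Z_s Z_tᵀ is the best rank-d
approximation of S; the test suite verifies exactness at d = n and
monotone error decay in d. SVD columns are defined only up to sign, so
each column is canonicalized (largest-magnitude entry of the Z_s column
made positive, the Z_t column flipped jointly) to make embeddings
reproducible bit-for-bit. Because the MAN is undirected, S is symmetric,
Z_t equals Z_s up to column signs, and the Z_s row alone is the node's
behavior feature.

One property worth recording: for symmetric A, every Katz S = f(A) shares
A's eigenvectors, and f is monotone on the dominant spectrum — so β only
rescales embedding columns. Scale-invariant classifiers (trees) are
therefore insensitive to β; it matters only for magnitude-sensitive
downstream uses.

The default embedding dimension is d = 64, matching the attribute latent
dimension so the two feature families carry equal width in the
concatenated pair representation.

## Attribute features

* **RNA (miRNA, lncRNA):** 3-mer frequencies over {A,C,G,U}, window
  length 3, stride 1, counts divided by the number of windows
  (length − 2), giving a 64-vector summing to 1 for any sequence of
  length ≥ 3. DNA-notation input is accepted via T→U; other characters
  are dropped with a warning.
* **Protein:** the 20 amino acids are collapsed into 4 side-chain
  polarity groups — {A,V,L,I,M,F,W,P}, {G,S,T,C,N,Q,Y}, {R,K,H}, {D,E} —
  and the same 3-mer scheme is applied to the reduced string (again 64
  features). Nonstandard residues (B, J, O, U, X, Z) are dropped with a
  warning.
* **Drug:** folded Morgan/ECFP circular fingerprint of the SMILES,
  radius 2, 1024 bits (RDKit). Unparsable SMILES raise by default; a
  permissive flag substitutes a zero vector.
* **Disease:** each disease's MeSH tree numbers induce an ancestor DAG
  (the parent of tree number X.Y is X; multiple tree numbers contribute
  the union of their ancestor sets, each full tree number being an "is
  the disease itself" root). The semantic contribution of ancestor t is
  D1_D(t) = Δ·max over t's children in the DAG, with D1_D(D) = 1,
  computed by depth-first traversal with cycle detection. Similarity is
  the Jaccard-style ratio S1(i,j) = Σ_{shared t}(D1_i(t)+D1_j(t)) /
  (DV1(i)+DV1(j)), which is symmetric, 1 on the diagonal, and bounded in
  [0,1]. The decay factor Δ = 0.5 follows the convention of the DAG
  semantic-similarity literature. A disease's attribute vector is its
  row of the full pairwise S1 matrix (length = number of diseases);
  diseases without a MeSH entry get a zero row but still receive behavior
  features.

## Autoencoder

Raw attribute widths differ by type (64, 1024, n_diseases), so one
autoencoder per molecule type maps them to a shared latent dimension
(default 64). Architecture: input → 256 → latent → 256 → input.
Rectifiers f(t) = max(0, W t + b) on hidden and latent layers; the
reconstruction layer is linear, because a rectified output unit whose
pre-activation goes negative receives no gradient and dies permanently.
Inputs are centered on the per-type training mean inside the trainer
(attribute vectors are non-negative and far from zero mean; training on
raw values drives correlated gradients that collapse the rectified latent
units together) — encodings remain non-negative since the latent layer
stays rectified. Training is seeded mini-batch gradient descent on the
summed squared reconstruction error, learning rate 1e-2, batch 32, 300
epochs, He-initialized weights, gradients averaged over the batch; the
loss trace (entry 0 = pre-training loss) is retained, and identical seeds
reproduce identical traces. Types whose raw width already equals the
latent width are still passed through their autoencoder so all encoded
attributes live in comparable learned spaces. No denoising, dropout,
weight tying, or hyperparameter search.

## Link prediction and evaluation

A candidate pair is represented as
[behavior_i | attribute_i | behavior_j | attribute_j] with (i, j) in
canonical (type, id) order, so an unordered pair always produces the same
row; feature modes zero out the attribute blocks ("behavior"), the
behavior blocks ("attribute"), or neither ("combined"), keeping row
length constant across ablations.

**Negatives.** For each association category, as many unordered node
pairs of the matching types as there are positives (ratio 1:1) are drawn
uniformly without replacement from pairs that are edges nowhere in the
*full* network. Category matching prevents the classifier from exploiting
node-type identity; excluding all known edges avoids training on false
negatives. Negative construction is a protocol choice of this package —
curated association databases carry no verified non-associations.

**Classifier.** Gradient-boosted decision trees
(`HistGradientBoostingClassifier`), 500 boosting rounds of default
shallow trees, fixed seed, no tuning — the many-shallow-trees default
regime of the mainstream GBDT implementations. The classifier is a
pluggable hook (`fit(rows, labels)` / `score_samples(rows)`), so any
scikit-learn-style probabilistic classifier can be swapped in. Label
metrics threshold the probability at 0.5.

**Cross-validation.** Edges are split into five disjoint folds
(deterministic per seed). Per fold, the held-out positives are removed
from the graph *before* the behavior embedding is recomputed — an
assertion verifies the test edges are absent from the embedding input —
and the classifier is trained on the remaining folds' positives plus
matched negatives. Nodes disconnected by fold removal keep zero behavior
vectors rather than being dropped, so their test pairs remain scoreable.
The category case study folds only the chosen category's edges; all other
categories always remain in the embedding graph, matching the protocol of
training-set-plus-context embedding. AUC is trapezoidal integration of
the ROC (equivalent to concordant-pair counting with half-credit ties);
AUPR integrates precision over recall. Metrics with vanishing
denominators are set to 0 and flagged by name rather than raising.

## Synthetic fixtures and the desk-scale studies

`generate_man` plants recoverable structure: each node draws a latent
z ~ N(0, I_8), and each legal pair (i, j) is an edge with probability
logistic(z_i·z_j + c), the per-category intercept c calibrated by
bisection to a target density (raising an error if the realized density
misses by more than 20%). Walk-based proximities of such a graph are
approximately low-rank, so HOPE can recover the latent geometry — a
principled positive control. The `erdos_renyi` mode draws edges uniformly
at the same density: a no-signal negative control on which any
leakage-free evaluation must sit at chance. Sequence, SMILES, and
MeSH-table generators emit exactly the file formats the pipeline reads;
sequences are uniform random residues, SMILES are drawn from a built-in
catalogue of ~50 valid drug-like molecules, and tree numbers are random
dotted paths over a five-root forest.

The built-in desk-scale studies (`manlink.experiments`) use 300 nodes
(40/80/80/50/50 per type), latent dimension 8, and per-category edge
density 0.12, giving mean degree ≈ 26 — the same order of connectivity as
the large curated network this pipeline targets. At this scale the
embedding dimension is set to 8, the generative rank (the oracle
dimension of a simulation study; a 64-dimensional embedding of a 300-node
sparse graph would mostly carry spectral noise), and the attribute latent
dimension matches it at 8, preserving the equal-width principle of the
full-scale defaults. The ablation study uses the package's own
featurization applied to the fixture's random sequences/SMILES/MeSH
tables: these attributes are uninformative about the planted edges *by
construction*, which is the honest "attributes carry no signal"
condition (i.i.d. Gaussian node vectors would instead act as node
fingerprints and measure identity memorization, not feature ablation).

What the synthetic studies do and do not show: they validate the
machinery — leakage-free protocol, planted-signal recovery, chance-level
behavior without signal, metric correctness — under a low-rank logistic
edge model with balanced negatives. They do not emulate the heavy-tailed
degree distributions, category imbalance, or attribute informativeness of
curated databases, so absolute performance numbers on real data cannot be
extrapolated from them.

## Numerical choices and degenerate inputs

- Sequences shorter than 3 residues give zero k-mer vectors plus a
  warning; empty graphs are rejected where an adjacency is required.
- Katz with β ≥ 1/σ_max raises (divergent series); degree-normalized
  measures raise on zero-degree rows (impossible on a built MAN, possible
  on raw adjacencies).
- Ties in scores are handled by the grouped ROC sweep (half credit), and
  MCC returns 0 with a flag when any confusion-matrix margin is zero.
- All randomness (fold assignment, negative sampling, classifier,
  generators, autoencoder init/shuffling) flows through named integer
  seeds; SVD sign canonicalization removes the one remaining source of
  run-to-run variation.

## Known limitations

- No identifier cross-mapping or database ETL: inputs must arrive with
  unified per-type namespaces.
- The autoencoder is a fixed small architecture trained by plain SGD;
  it is adequate for dimension unification, not a generative model.
- The dense-S embedding path scales to a few thousand nodes; truly large
  networks would need an implicitly restarted partial generalized SVD,
  which is out of scope.
- Balanced 1:1 negatives overstate precision relative to the extreme
  class imbalance of real screening settings; AUPR under realistic
  imbalance will be substantially lower.
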
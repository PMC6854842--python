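# manlink

Link prediction on a heterogeneous **Molecular Association Network (MAN)**
of lncRNAs, miRNAs, proteins, drugs, and diseases.

Cellular function and disease emerge from webs of interactions that cross
molecule classes: a miRNA silences an mRNA, the encoded protein binds a
drug, the drug treats a disease, the disease is associated with a lncRNA.
`manlink` treats all of these as one undirected network with five node
types and nine association categories (miRNA–lncRNA, miRNA–disease,
miRNA–protein, lncRNA–protein, protein–disease, protein–protein,
lncRNA–disease, drug–disease, drug–protein) and asks, for any candidate
pair of molecules, *how likely is an association?* The intended audience
is computational biologists prioritizing candidate associations (e.g.
miRNA–disease links) for experimental follow-up.

## Method

Each node gets two complementary feature vectors:

**Behavior (network embedding).** High-Order Proximity preserved
Embedding (HOPE) writes a walk-based proximity matrix as a product of
sparse factors, S = M_g⁻¹ M_l, and factorizes it by truncated SVD:

    S ≈ U_d Σ_d V_dᵀ,   Z_s = U_d Σ_d^{1/2},   Z_t = V_d Σ_d^{1/2},

so that Z_s Z_tᵀ is the best rank-d approximation of S in Frobenius norm.
The default proximity is the Katz index S = Σ_{k≥1} βᵏAᵏ = (I − βA)⁻¹βA
with β = 0.5/σ_max(A); common-neighbors, Adamic–Adar, and rooted PageRank
are also available. The network is undirected, so S is symmetric and a
node's Z_s row is its behavior feature.

**Attribute (intrinsic descriptor).** 3-mer frequency vectors for miRNA
and lncRNA sequences (4³ = 64 features over {A,C,G,U}); the same 3-mer
scheme for proteins after collapsing the 20 amino acids into 4 side-chain
polarity groups; Morgan (ECFP-style) fingerprints for drug SMILES; and,
for diseases, a row of the pairwise semantic-similarity matrix computed
on MeSH descriptor DAGs, where an ancestor t of disease D contributes
D1_D(t) = Δ·max over children t′ of D1_D(t′) (with D1_D(D) = 1, Δ = 0.5)
and S1(i,j) = Σ_{t∈N_i∩N_j}(D1_i(t)+D1_j(t)) / (DV1(i)+DV1(j)). A dense
autoencoder per node type compresses these heterogeneous widths to one
shared latent dimension.

A pair (i, j) in canonical order is represented as
[behavior_i | attribute_i | behavior_j | attribute_j] and scored by
gradient-boosted decision trees. Evaluation is **leakage-free five-fold
cross-validation**: held-out edges are removed from the graph *before*
the embedding is recomputed, negatives are balanced 1:1 and
category-matched, and Acc/Sen/Spec/Prec/MCC/AUC/AUPR are reported per
fold. A per-category "case study" mode folds only one association
category (e.g. miRNA–disease) while all other edges keep informing the
embedding.

A synthetic-fixture generator produces complete, download-free inputs
(typed edge lists, FASTA, SMILES and MeSH-like tables) with plantable
low-rank structure, so the whole pipeline can be exercised and validated
end to end without the curated source databases.

## Worked example

Generate a 300-node synthetic network with planted rank-8 structure,
build the MAN, featurize, and cross-validate each feature mode:

```sh
manlink simulate --seed 7 --out demo/fixture
manlink build --edges demo/fixture/edges --out demo/man
manlink featurize --graph demo/man/graph.tsv \
    --mirna-fasta demo/fixture/miRNA.fasta \
    --lncrna-fasta demo/fixture/lncRNA.fasta \
    --protein-fasta demo/fixture/protein.fasta \
    --drugs demo/fixture/drugs.tsv --mesh demo/fixture/mesh.tsv \
    --dim 8 --out demo/attrs
manlink cv --graph demo/man/graph.tsv \
    --attributes demo/attrs/attributes.tsv \
    --features behavior attribute combined \
    --dim 8 --seed 0 --out demo/cv
manlink case-study --graph demo/man/graph.tsv \
    --category miRNA-disease --dim 8 --seed 0 --out demo/case
```

which prints (build summary abridged):

```
"n_nodes": 300, "n_edges": 3857
[behavior] mean acc=0.7317 auc=0.8140 aupr=0.8085 mcc=0.4669
[attribute] mean acc=0.5112 auc=0.5236 aupr=0.5265 mcc=0.0303
[combined] mean acc=0.7317 auc=0.8121 aupr=0.8070 mcc=0.4674
[miRNA-disease] mean acc=0.7044 auc=0.7760
```

Read: the network-behavior embedding recovers the planted structure
(AUC ≈ 0.81 despite the test edges being absent from the embedding
graph), the attribute features of *random* synthetic sequences carry
essentially no signal (AUC ≈ 0.52, chance level), and combining them
neither helps nor hurts — on real data, where attributes are informative,
the combination is what the pipeline is built for. The case study shows
that a single category can be predicted while the rest of the network
supplies context. Full per-fold reports and ROC/PR curve points are
written under `demo/cv/` and `demo/case/`.

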
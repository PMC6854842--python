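"""Intrinsic ("attribute") features of network nodes.

* RNA nodes (miRNA, lncRNA): normalized 3-mer frequencies over {A,C,G,U}
  (64 = 4^3 features; DNA-notation inputs are accepted via T->U mapping).
* Proteins: the 20 amino acids are collapsed to 4 side-chain polarity
  groups and the same 3-mer frequency is taken over the reduced alphabet.
* Drugs: folded Morgan (ECFP-style) circular fingerprints of their SMILES.
* Diseases: a row of the pairwise semantic-similarity matrix computed on
  MeSH descriptor DAGs with a per-level decay factor delta.

All features are finite and fixed-length within a molecule type; the
autoencoder downstream compresses each type to a common latent dimension.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "DiseaseDAG",
    "rna_kmer",
    "reduce_protein",
    "protein_kmer",
    "kmer_frequencies",
    "drug_fingerprint",
    "semantic_contribution",
    "dv",
    "disease_similarity",
    "disease_attribute",
    "disease_similarity_matrix",
    "dag_from_tree_numbers",
    "read_fasta",
    "read_drug_table",
    "read_mesh_table",
    "PROTEIN_GROUPS",
]

RNA_ALPHABET = ("A", "C", "G", "U")
GROUP_ALPHABET = ("1", "2", "3", "4")

# Side-chain polarity groups: 1 = nonpolar/hydrophobic, 2 = polar uncharged,
# 3 = basic, 4 = acidic.
PROTEIN_GROUPS: dict[str, str] = {
    **{aa: "1" for aa in "AVLIMFWP"},
    **{aa: "2" for aa in "GSTCNQY"},
    **{aa: "3" for aa in "RKH"},
    **{aa: "4" for aa in "DE"},
}


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    alphabet: str  # "RNA" | "protein"
    residues: str


def _kmer_index(alphabet: Sequence[str], k: int) -> dict[str, int]:
    return {
        "".join(p): i
        for i, p in enumerate(itertools.product(alphabet, repeat=k))
    }


def kmer_frequencies(seq: str, alphabet: Sequence[str], k: int = 3) -> np.ndarray:
    """Sliding-window k-mer frequencies (stride 1), length |alphabet|^k.

    Counts are divided by the number of windows (len - k + 1) so the vector
    sums to 1 for any sequence of length >= k; shorter sequences give the
    zero vector with a warning.
    """
    idx = _kmer_index(alphabet, k)
    out = np.zeros(len(idx))
    n_windows = len(seq) - k + 1
    if n_windows < 1:
        warnings.warn(f"sequence shorter than k={k}; zero k-mer vector")
        return out
    for i in range(n_windows):
        out[idx[seq[i : i + k]]] += 1.0
    return out / n_windows


def _clean(seq: str, allowed: frozenset[str], what: str) -> str:
    bad = set(seq) - allowed
    if bad:
        warnings.warn(f"dropping {what} characters {sorted(bad)}")
        seq = "".join(c for c in seq if c in allowed)
    return seq


def rna_kmer(record: SequenceRecord, k: int = 3) -> np.ndarray:
    """3-mer frequency vector of an RNA sequence (AAA..UUU, 64 entries)."""
    seq = record.residues.upper().replace("T", "U")
    seq = _clean(seq, frozenset(RNA_ALPHABET), "non-ACGU")
    return kmer_frequencies(seq, RNA_ALPHABET, k)


def reduce_protein(record: SequenceRecord) -> str:
    """Replace each residue by its polarity-group symbol (length preserved;
    nonstandard residues dropped with a warning)."""
    seq = record.residues.upper()
    seq = _clean(seq, frozenset(PROTEIN_GROUPS), "nonstandard amino-acid")
    return "".join(PROTEIN_GROUPS[c] for c in seq)


def protein_kmer(record: SequenceRecord, k: int = 3) -> np.ndarray:
    """3-mer frequencies of the 4-group reduced protein string (64 entries)."""
    return kmer_frequencies(reduce_protein(record), GROUP_ALPHABET, k)


def drug_fingerprint(
    smiles: str, radius: int = 2, n_bits: int = 1024, permissive: bool = False
) -> np.ndarray:
    """Folded Morgan circular fingerprint of a SMILES string as a 0/1 vector."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        if permissive:
            warnings.warn(f"unparsable SMILES {smiles!r}; zero fingerprint")
            return np.zeros(n_bits)
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return np.array(fp, dtype=float)


# ---------------------------------------------------------------------------
# Disease semantic similarity over MeSH descriptor DAGs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiseaseDAG:
    """Ancestor DAG of one disease.

    ``nodes`` contains the disease's own descriptor node(s) plus every
    ancestor; ``edges`` are (parent, child) links; ``roots`` are the
    disease's own nodes (the t = D case of the contribution recursion).
    With MeSH tree numbers, nodes are tree-number strings and the parent of
    ``X.Y`` is ``X``.
    """

    disease: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    roots: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        roots = self.roots or frozenset({self.disease})
        object.__setattr__(self, "roots", roots)
        if not roots <= self.nodes:
            raise ValueError("disease node(s) must be members of the DAG")
        for p, c in self.edges:
            if p not in self.nodes or c not in self.nodes:
                raise ValueError(f"edge ({p}, {c}) references unknown node")


def _children(dag: DiseaseDAG) -> dict[str, list[str]]:
    ch: dict[str, list[str]] = {n: [] for n in dag.nodes}
    for p, c in dag.edges:
        ch[p].append(c)
    return ch


def semantic_contribution(dag: DiseaseDAG, delta: float = 0.5) -> dict[str, float]:
    """Per-node semantic contribution to the disease.

    The disease's own node contributes 1; any ancestor t contributes
    delta * max over its children t' within the DAG — i.e. the contribution
    decays geometrically with distance from the disease.
    """
    if not (0 < delta <= 1):
        raise ValueError("delta must lie in (0, 1]")
    children = _children(dag)
    contrib: dict[str, float] = {}
    state: dict[str, int] = {}  # 1 = on stack, 2 = done

    def visit(t: str) -> float:
        if state.get(t) == 1:
            raise ValueError(f"cycle detected at node {t!r}")
        if t in contrib:
            return contrib[t]
        state[t] = 1
        if t in dag.roots:
            val = 1.0
        else:
            kids = children[t]
            if not kids:
                raise ValueError(
                    f"node {t!r} has no path to the disease {dag.disease!r}"
                )
            val = delta * max(visit(c) for c in kids)
        state[t] = 2
        contrib[t] = val
        return val

    for node in dag.nodes:
        visit(node)
    return contrib


def dv(dag: DiseaseDAG, delta: float = 0.5) -> float:
    """Total semantic value: sum of contributions over all DAG nodes (>= 1)."""
    return float(sum(semantic_contribution(dag, delta).values()))


def disease_similarity(dag_i: DiseaseDAG, dag_j: DiseaseDAG, delta: float = 0.5) -> float:
    """Jaccard-style semantic similarity in [0, 1].

    Shared DAG nodes contribute the sum of their contributions to each
    disease, normalized by the two total semantic values.
    """
    ci = semantic_contribution(dag_i, delta)
    cj = semantic_contribution(dag_j, delta)
    shared = set(ci) & set(cj)
    num = sum(ci[t] + cj[t] for t in shared)
    den = sum(ci.values()) + sum(cj.values())
    return num / den


def disease_similarity_matrix(
    dags: Mapping[str, DiseaseDAG], delta: float = 0.5
) -> tuple[list[str], np.ndarray]:
    """Full pairwise similarity matrix in sorted disease order."""
    order = sorted(dags)
    contribs = {d: semantic_contribution(dags[d], delta) for d in order}
    totals = {d: sum(c.values()) for d, c in contribs.items()}
    n = len(order)
    S = np.eye(n)
    for i in range(n):
        ci = contribs[order[i]]
        for j in range(i + 1, n):
            cj = contribs[order[j]]
            shared = set(ci) & set(cj)
            if shared:
                num = sum(ci[t] + cj[t] for t in shared)
                S[i, j] = S[j, i] = num / (totals[order[i]] + totals[order[j]])
    return order, S


def disease_attribute(
    disease_id: str, all_dags: Mapping[str, DiseaseDAG], delta: float = 0.5
) -> np.ndarray:
    """This disease's row of the full similarity matrix, in sorted order.

    A disease without a MeSH entry gets a zero row (it still receives a
    behavior feature from the network).
    """
    order, S = disease_similarity_matrix(all_dags, delta)
    if disease_id not in all_dags:
        warnings.warn(f"disease {disease_id!r} has no MeSH entry; zero attribute")
        return np.zeros(len(order))
    return S[order.index(disease_id)]


def dag_from_tree_numbers(disease_id: str, tree_numbers: Iterable[str]) -> DiseaseDAG:
    """Build a disease's ancestor DAG from its MeSH tree numbers.

    Each dotted tree number (e.g. ``C04.557.337``) denotes one placement of
    the disease; its proper prefixes are the ancestors (the parent of
    ``X.Y`` is ``X``). A disease with several tree numbers gets the union
    of the ancestor sets, with each full tree number a root node of the
    disease itself.
    """
    tns = [tn.strip() for tn in tree_numbers if tn.strip()]
    if not tns:
        raise ValueError(f"disease {disease_id!r} has no tree numbers")
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for tn in tns:
        parts = tn.split(".")
        prefixes = [".".join(parts[: i + 1]) for i in range(len(parts))]
        nodes.update(prefixes)
        for parent, child in zip(prefixes, prefixes[1:]):
            edges.add((parent, child))
    return DiseaseDAG(
        disease=disease_id,
        nodes=frozenset(nodes),
        edges=frozenset(edges),
        roots=frozenset(tns),
    )


# ---------------------------------------------------------------------------
# Input readers
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, alphabet: str) -> list[SequenceRecord]:
    """FASTA records; the node id is the header up to the first whitespace."""
    return [
        SequenceRecord(id=rec.id, alphabet=alphabet, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def _read_two_column_tsv(path: str | Path) -> list[tuple[str, str]]:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            rows.append((fields[0].strip(), fields[1].strip()))
    return rows


def read_drug_table(path: str | Path) -> dict[str, str]:
    """TSV of (drug id, SMILES)."""
    return dict(_read_two_column_tsv(path))


def read_mesh_table(path: str | Path) -> dict[str, DiseaseDAG]:
    """TSV of (disease id, semicolon-separated MeSH tree numbers)."""
    return {
        did: dag_from_tree_numbers(did, tns.split(";"))
        for did, tns in _read_two_column_tsv(path)
    }
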
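"""Synthetic molecular-association fixtures for download-free end-to-end runs.

``generate_man`` plants recoverable low-rank structure: every node gets a
latent Gaussian vector z and each legal type pair (i, j) becomes an edge
with probability logistic(z_i . z_j + c), where the per-category intercept
c is calibrated by bisection so the expected edge count matches the target
density. Because walk-based proximities of such a graph are themselves
approximately low-rank, the planted structure is a principled positive
control for the embedding + classifier pipeline; the ``erdos_renyi`` mode
generates edges uniformly at the same density as a no-signal negative
control.

The remaining generators emit exactly the file formats the pipeline reads:
FASTA sequences, a drug SMILES table, and a MeSH-like tree-number table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .man_graph import (
    Association,
    AssociationCategory,
    MANGraph,
    MoleculeType,
    Node,
    build_man,
)

__all__ = [
    "SyntheticConfig",
    "generate_man",
    "generate_sequences",
    "generate_drug_table",
    "generate_mesh_table",
    "write_fixture_tree",
]

DEFAULT_COUNTS: dict[MoleculeType, int] = {
    MoleculeType.LNCRNA: 40,
    MoleculeType.MIRNA: 80,
    MoleculeType.PROTEIN: 80,
    MoleculeType.DRUG: 50,
    MoleculeType.DISEASE: 50,
}

_ID_PREFIX = {
    MoleculeType.LNCRNA: "lnc",
    MoleculeType.MIRNA: "mir",
    MoleculeType.PROTEIN: "pro",
    MoleculeType.DRUG: "drg",
    MoleculeType.DISEASE: "dis",
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_per_type: Mapping[MoleculeType, int] = field(
        default_factory=lambda: dict(DEFAULT_COUNTS)
    )
    latent_dim: int = 8
    edge_density: float = 0.12
    structure: str = "planted"  # "planted" | "erdos_renyi"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.edge_density < 1):
            raise ValueError("edge_density must lie in (0, 1)")
        if self.structure not in ("planted", "erdos_renyi"):
            raise ValueError("structure must be 'planted' or 'erdos_renyi'")
        for t, n in self.n_per_type.items():
            if n < 2:
                raise ValueError(f"need >= 2 nodes of type {t.value}")


def _node_ids(config: SyntheticConfig) -> dict[MoleculeType, list[Node]]:
    return {
        t: [Node(t, f"{_ID_PREFIX[t]}{i + 1:03d}") for i in range(n)]
        for t, n in config.n_per_type.items()
    }


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_intercept(logits: np.ndarray, target: float) -> float:
    """Bisection for c with mean(sigmoid(logits + c)) ~= target density."""
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if float(np.mean(_sigmoid(logits + mid))) < target:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    got = float(np.mean(_sigmoid(logits + c)))
    if abs(got - target) > 0.2 * target:
        raise ValueError(
            f"target density {target} unachievable (closest {got:.4g})"
        )
    return c


def generate_man(config: SyntheticConfig) -> tuple[MANGraph, dict[str, np.ndarray]]:
    """Synthetic network plus the ground-truth latent vectors per node id."""
    rng = np.random.default_rng(config.seed)
    nodes = _node_ids(config)
    latents = {
        node.id: rng.standard_normal(config.latent_dim)
        for t in sorted(nodes, key=lambda t: t.value)
        for node in nodes[t]
    }

    associations: list[Association] = []
    for category in AssociationCategory:
        ta, tb = category.type_pair
        if ta not in nodes or tb not in nodes:
            continue
        na, nb = nodes[ta], nodes[tb]
        Za = np.vstack([latents[n.id] for n in na])
        Zb = np.vstack([latents[n.id] for n in nb])
        logits = Za @ Zb.T
        if category is AssociationCategory.PROTEIN_PROTEIN:
            iu = np.triu_indices(len(na), k=1)  # no synthetic self-loops
            flat_logits = logits[iu]
            pairs = list(zip(iu[0], iu[1]))
        else:
            flat_logits = logits.ravel()
            pairs = [(i, j) for i in range(len(na)) for j in range(len(nb))]
        if config.structure == "planted":
            c = _calibrate_intercept(flat_logits, config.edge_density)
            probs = _sigmoid(flat_logits + c)
        else:
            probs = np.full(len(pairs), config.edge_density)
        draws = rng.random(len(pairs))
        for (i, j), p, u in zip(pairs, probs, draws):
            if u < p:
                associations.append(Association(na[i], nb[j], category))
    return build_man(associations), latents


def generate_sequences(
    ids: Iterable[str],
    alphabet: str = "RNA",
    length_range: tuple[int, int] = (60, 200),
    seed: int = 0,
) -> list[tuple[str, str]]:
    """(id, sequence) records of uniform random residues."""
    lo, hi = length_range
    if lo < 3:
        raise ValueError("minimum sequence length is 3")
    letters = "ACGU" if alphabet == "RNA" else "ACDEFGHIKLMNPQRSTVWY"
    rng = np.random.default_rng(seed)
    out = []
    for nid in ids:
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(letters), size=length))
        out.append((nid, seq))
    return out


# ~50 valid drug-like small-molecule SMILES used as a substitution basis.
_BASE_SMILES = [
    "CC(=O)OC1=CC=CC=C1C(=O)O", "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O",
    "CN1C=NC2=C1C(=O)N(C(=O)N2C)C", "CC(=O)NC1=CC=C(C=C1)O",
    "C1=CC=C(C=C1)C(=O)O", "OC(=O)C1=CC=CC=C1O", "C1CCCCC1",
    "C1=CC=C2C=CC=CC2=C1", "CCO", "CCN(CC)CC", "CC(C)O", "CCCCO",
    "CC(=O)O", "CCC(=O)O", "NC(=O)C1=CC=CC=C1", "NC1=CC=C(C=C1)S(N)(=O)=O",
    "OCC1OC(O)C(O)C(O)C1O", "CN(C)CCC1=CNC2=CC=CC=C12",
    "NCCC1=CC(O)=C(O)C=C1", "CC(N)CC1=CC=CC=C1", "CN1CCC23C4OC(=O)C2=C1CC3C=C4",
    "ClC1=CC=CC=C1", "FC1=CC=CC=C1", "BrC1=CC=CC=C1", "OC1=CC=CC=C1",
    "NC1=CC=CC=C1", "CC1=CC=CC=C1", "COC1=CC=CC=C1", "CSC1=CC=CC=C1",
    "O=C1NC(=O)NC(=O)C1", "C1=CN=CC=C1", "C1=CC=NC=C1C(N)=O",
    "OC(=O)CC(O)(CC(O)=O)C(O)=O", "NC(CC(O)=O)C(O)=O", "NC(CCC(O)=O)C(O)=O",
    "NC(CO)C(O)=O", "NC(CS)C(O)=O", "CC(C)(C)NCC(O)C1=CC(O)=CC(O)=C1",
    "CC1=CC(C)=CC(C)=C1", "OC(=O)C=CC1=CC=CC=C1", "O=CC1=CC=CC=C1",
    "CC(=O)C1=CC=CC=C1", "OCC1=CC=CC=C1", "N#CC1=CC=CC=C1",
    "O=[N+]([O-])C1=CC=CC=C1", "CC1CCCCC1", "OC1CCCCC1", "O=C1CCCCC1",
    "C1CCOC1", "C1CCNC1", "C1CCSC1",
]


def generate_drug_table(ids: Iterable[str], seed: int = 0) -> list[tuple[str, str]]:
    """(id, SMILES) rows; all SMILES are valid by construction."""
    rng = np.random.default_rng(seed)
    # substitution variants: optionally methylate an aromatic ring carbon
    out = []
    for nid in ids:
        base = _BASE_SMILES[int(rng.integers(len(_BASE_SMILES)))]
        if rng.random() < 0.3 and "C1=CC=CC=C1" in base:
            base = base.replace("C1=CC=CC=C1", "C1=CC=C(C)C=C1", 1)
        out.append((nid, base))
    return out


def generate_mesh_table(
    ids: Iterable[str],
    max_depth: int = 4,
    branching: int = 3,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """(id, semicolon-separated tree numbers) rows over random rooted trees.

    Tree numbers are dotted paths like ``C03.141.072``; shared prefixes
    between diseases give them shared DAG ancestors and hence nonzero
    semantic similarity.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    rng = np.random.default_rng(seed)
    roots = [f"C{r:02d}" for r in range(1, 6)]
    out = []
    for nid in ids:
        n_numbers = 1 + int(rng.random() < 0.3)
        tns = set()
        while len(tns) < n_numbers:
            depth = int(rng.integers(1, max_depth + 1))
            parts = [roots[int(rng.integers(len(roots)))]]
            parts += [
                f"{int(rng.integers(branching)) * 100 + 141:03d}"
                for _ in range(depth - 1)
            ]
            tns.add(".".join(parts))
        out.append((nid, ";".join(sorted(tns))))
    return out


def write_fixture_tree(out_dir: str | Path, config: SyntheticConfig) -> MANGraph:
    """Materialize a full input tree (edge TSVs, FASTA, drug and MeSH
    tables, ground-truth JSON) and return the generated graph."""
    out_dir = Path(out_dir)
    (out_dir / "edges").mkdir(parents=True, exist_ok=True)
    graph, latents = generate_man(config)

    by_cat: dict[AssociationCategory, list[Association]] = {}
    for a in graph.edges:
        by_cat.setdefault(a.category, []).append(a)
    for category, assocs in by_cat.items():
        type_a, _ = category.type_pair
        with open(out_dir / "edges" / f"{category.value}.tsv", "w", encoding="utf-8") as fh:
            fh.write("#source\ttarget\n")
            for a in assocs:
                s, t = a.canonical()
                if s.type is not type_a:  # column order must match the category
                    s, t = t, s
                fh.write(f"{s.id}\t{t.id}\n")

    seq_seed = config.seed + 1
    for mtype, fname, alphabet in (
        (MoleculeType.MIRNA, "miRNA.fasta", "RNA"),
        (MoleculeType.LNCRNA, "lncRNA.fasta", "RNA"),
        (MoleculeType.PROTEIN, "protein.fasta", "protein"),
    ):
        ids = [n.id for n in graph.nodes_of_type(mtype)]
        recs = generate_sequences(ids, alphabet, seed=seq_seed)
        seq_seed += 1
        with open(out_dir / fname, "w", encoding="utf-8") as fh:
            for nid, seq in recs:
                fh.write(f">{nid}\n{seq}\n")

    drug_ids = [n.id for n in graph.nodes_of_type(MoleculeType.DRUG)]
    with open(out_dir / "drugs.tsv", "w", encoding="utf-8") as fh:
        fh.write("#id\tsmiles\n")
        for nid, smi in generate_drug_table(drug_ids, seed=config.seed + 10):
            fh.write(f"{nid}\t{smi}\n")

    disease_ids = [n.id for n in graph.nodes_of_type(MoleculeType.DISEASE)]
    with open(out_dir / "mesh.tsv", "w", encoding="utf-8") as fh:
        fh.write("#id\ttree_numbers\n")
        for nid, tns in generate_mesh_table(disease_ids, seed=config.seed + 11):
            fh.write(f"{nid}\t{tns}\n")

    with open(out_dir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "seed": config.seed,
                "structure": config.structure,
                "latent_dim": config.latent_dim,
                "edge_density": config.edge_density,
                "latents": {k: v.tolist() for k, v in latents.items()},
            },
            fh,
        )
        fh.write("\n")
    return graph
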
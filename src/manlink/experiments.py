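"""Desk-scale evaluation studies on synthetic networks.

These are the package's built-in positive/negative-control experiments:
a ~300-node association network with planted rank-8 latent structure is
the positive control (the embedding + classifier pipeline must recover
the signal), and an Erdos-Renyi network of identical size is the
no-signal negative control (performance must sit at chance).

Study conditions: the generator defaults of :class:`SyntheticConfig`
(latent dim 8, per-category edge density 0.12), behavior-embedding
dimension 8 (the generative rank — the oracle dimension for a simulation
study), and attribute latent dimension 8 so behavior and attribute blocks
carry equal weight. The full-scale pipeline default for both dimensions
is 64.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .attributes import (
    SequenceRecord,
    dag_from_tree_numbers,
    disease_similarity_matrix,
    drug_fingerprint,
    protein_kmer,
    rna_kmer,
)
from .autoencoder import AutoencoderConfig, encode, train_autoencoder
from .hope import ProximityConfig
from .link_prediction import CVConfig, CVReport, category_case_study, cross_validate
from .man_graph import AssociationCategory, MANGraph, MoleculeType
from .synthetic import (
    SyntheticConfig,
    generate_drug_table,
    generate_man,
    generate_mesh_table,
    generate_sequences,
)

__all__ = [
    "DESK_EMBED_DIM",
    "desk_graph",
    "desk_attributes",
    "desk_cv_config",
    "desk_cross_validate",
    "desk_case_study",
]

DESK_EMBED_DIM = 8  # generative rank of the planted control
DESK_ATTR_DIM = 8


def desk_graph(
    seed: int, structure: str = "planted"
) -> tuple[MANGraph, dict[str, np.ndarray]]:
    """The desk-scale synthetic network at the default study conditions."""
    return generate_man(SyntheticConfig(seed=seed, structure=structure))


def desk_attributes(graph: MANGraph, seed: int) -> dict[str, np.ndarray]:
    """Attribute features for every node of a desk-scale network.

    Runs the real featurization on synthetic inputs (random sequences,
    catalogue SMILES, random MeSH trees), then one autoencoder per type
    down to the desk attribute dimension. By construction the attributes
    carry no information about the planted edges, so they act as a
    realistic uninformative-attribute condition for ablations.
    """
    raw: dict[MoleculeType, dict[str, np.ndarray]] = {}
    for mtype, alphabet, featurize in (
        (MoleculeType.MIRNA, "RNA", rna_kmer),
        (MoleculeType.LNCRNA, "RNA", rna_kmer),
        (MoleculeType.PROTEIN, "protein", protein_kmer),
    ):
        ids = [n.id for n in graph.nodes_of_type(mtype)]
        raw[mtype] = {
            nid: featurize(SequenceRecord(nid, alphabet, seq))
            for nid, seq in generate_sequences(ids, alphabet, seed=seed + 1)
        }
    drug_ids = [n.id for n in graph.nodes_of_type(MoleculeType.DRUG)]
    raw[MoleculeType.DRUG] = {
        nid: drug_fingerprint(smi)
        for nid, smi in generate_drug_table(drug_ids, seed=seed + 10)
    }
    disease_ids = [n.id for n in graph.nodes_of_type(MoleculeType.DISEASE)]
    dags = {
        nid: dag_from_tree_numbers(nid, tns.split(";"))
        for nid, tns in generate_mesh_table(disease_ids, seed=seed + 11)
    }
    order, S = disease_similarity_matrix(dags)
    raw[MoleculeType.DISEASE] = {nid: S[i] for i, nid in enumerate(order)}

    encoded: dict[str, np.ndarray] = {}
    for mtype in sorted(raw, key=lambda t: t.value):
        table = raw[mtype]
        if not table:
            continue
        ids = sorted(table)
        X = np.vstack([table[i] for i in ids])
        cfg = AutoencoderConfig(
            input_dim=X.shape[1],
            latent_dim=min(DESK_ATTR_DIM, X.shape[1]),
            seed=seed,
        )
        Z = encode(train_autoencoder(X, cfg), X)
        for nid, row in zip(ids, Z):
            encoded[nid] = row
    return encoded


def desk_cv_config(mode: str = "behavior", seed: int = 0) -> CVConfig:
    return CVConfig(
        mode=mode,
        proximity=ProximityConfig(dim=DESK_EMBED_DIM),
        fold_seed=seed,
        negative_seed=seed + 1,
        classifier_seed=seed + 2,
        attr_dim=DESK_ATTR_DIM,
    )


def desk_cross_validate(
    seed: int,
    structure: str = "planted",
    mode: str = "behavior",
    attributes: Mapping[str, np.ndarray] | None = None,
) -> CVReport:
    """Five-fold leakage-free CV of one desk-scale network."""
    graph, _ = desk_graph(seed, structure)
    if mode in ("attribute", "combined") and attributes is None:
        attributes = desk_attributes(graph, seed)
    return cross_validate(graph, desk_cv_config(mode, seed), attributes)


def desk_case_study(
    seed: int, category: AssociationCategory = AssociationCategory.MIRNA_DISEASE
) -> CVReport:
    """Single-category evaluation on the desk-scale planted network."""
    graph, _ = desk_graph(seed, "planted")
    return category_case_study(graph, category, desk_cv_config("behavior", seed))
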
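"""High-Order Proximity preserved Embedding (HOPE) of the association network.

HOPE writes a walk-based node-proximity matrix as a product of two sparse
factors, S = M_g^{-1} M_l, and factorizes S by truncated SVD into source and
target embeddings Z_s, Z_t with Z_s Z_t^T the best rank-d approximation of S.
Because the association network is undirected, S is symmetric and the Z_s
rows alone serve as the per-node "behavior" feature.

Supported proximity measures (A the adjacency, D the degree diagonal,
P = D^{-1} A the random-walk transition matrix):

====================  =======================  ==================
measure               M_g                      M_l
====================  =======================  ==================
katz                  I - beta * A             beta * A
common_neighbors      I                        A @ A
adamic_adar           I                        A @ D^{-1} @ A
rooted_pagerank       I - alpha * P            (1 - alpha) * I
====================  =======================  ==================

The Katz series sum_{k>=1} beta^k A^k converges iff beta < 1/sigma_max(A).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "ProximityConfig",
    "ProximityFactors",
    "NodeEmbedding",
    "proximity_factors",
    "proximity_matrix",
    "hope_embed",
    "reconstruction_error",
    "behavior_feature",
    "spectral_radius",
]

Measure = Literal["katz", "common_neighbors", "adamic_adar", "rooted_pagerank"]


@dataclass(frozen=True)
class ProximityConfig:
    measure: Measure = "katz"
    beta: float | None = None  # katz decay; default 0.5 / sigma_max(A)
    alpha: float = 0.5  # rooted-pagerank restart probability
    dim: int = 64

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("embedding dimension must be >= 1")
        if self.measure == "rooted_pagerank" and not (0 < self.alpha < 1):
            raise ValueError("rooted_pagerank requires alpha in (0, 1)")


@dataclass(frozen=True)
class ProximityFactors:
    """Sparse factors with S = M_g^{-1} M_l."""

    M_g: sp.csr_matrix
    M_l: sp.csr_matrix


@dataclass
class NodeEmbedding:
    Z_s: np.ndarray
    Z_t: np.ndarray
    node_order: list[str]
    config: ProximityConfig
    singular_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.Z_s.shape != self.Z_t.shape:
            raise ValueError("Z_s and Z_t must have identical shape")
        if self.Z_s.shape[0] != len(self.node_order):
            raise ValueError("embedding rows must align with node_order")

    @property
    def dim(self) -> int:
        return self.Z_s.shape[1]

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            cols = "\t".join(f"v{i + 1}" for i in range(self.dim))
            fh.write(f"#node_id\t{cols}\n")
            for node_id, row in zip(self.node_order, self.Z_s):
                vals = "\t".join(f"{v:.10g}" for v in row)
                fh.write(f"{node_id}\t{vals}\n")
        if sidecar is not None:
            meta = {
                "measure": self.config.measure,
                "beta": self.config.beta,
                "alpha": self.config.alpha,
                "dim": self.config.dim,
                "sign_canonicalized": True,
            }
            with open(sidecar, "w", encoding="utf-8") as fh:
                json.dump(meta, fh, indent=2)
                fh.write("\n")


def spectral_radius(A: np.ndarray | sp.spmatrix) -> float:
    """Largest singular value of A (== spectral radius for symmetric A)."""
    A = sp.csr_matrix(A)
    n = A.shape[0]
    if n <= 2:
        return float(np.linalg.norm(A.toarray(), 2))
    # fixed start vector: svds otherwise seeds randomly, which would make
    # the derived default Katz decay (and hence the embedding) jitter
    v0 = np.ones(n)
    return float(
        spla.svds(A.astype(float), k=1, v0=v0, return_singular_vectors=False)[0]
    )


def _degree_inverse(A: sp.csr_matrix) -> sp.dia_matrix:
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise ValueError("zero-degree node: degree-normalized proximity undefined")
    return sp.diags(1.0 / deg)


def proximity_factors(
    A: np.ndarray | sp.spmatrix, config: ProximityConfig
) -> ProximityFactors:
    """Assemble the sparse (M_g, M_l) pair for the configured measure."""
    A = sp.csr_matrix(A, dtype=float)
    n = A.shape[0]
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    eye = sp.identity(n, format="csr")

    if config.measure == "katz":
        beta = config.beta
        sigma = spectral_radius(A)
        if beta is None:
            beta = 0.5 / sigma if sigma > 0 else 0.5
        if sigma > 0 and beta >= 1.0 / sigma:
            raise ValueError(
                f"katz series diverges: beta={beta:.4g} >= 1/sigma_max={1.0 / sigma:.4g}"
            )
        return ProximityFactors(M_g=(eye - beta * A).tocsr(), M_l=(beta * A).tocsr())
    if config.measure == "common_neighbors":
        return ProximityFactors(M_g=eye, M_l=(A @ A).tocsr())
    if config.measure == "adamic_adar":
        Dinv = _degree_inverse(A)
        return ProximityFactors(M_g=eye, M_l=(A @ Dinv @ A).tocsr())
    if config.measure == "rooted_pagerank":
        P = _degree_inverse(A) @ A
        return ProximityFactors(
            M_g=(eye - config.alpha * P).tocsr(),
            M_l=((1.0 - config.alpha) * eye).tocsr(),
        )
    raise ValueError(f"unknown proximity measure {config.measure!r}")


def proximity_matrix(factors: ProximityFactors) -> np.ndarray:
    """Dense S = M_g^{-1} M_l via a sparse LU solve of M_g S = M_l."""
    M_g = factors.M_g.tocsc()
    M_l = factors.M_l.toarray()
    if (M_g != sp.identity(M_g.shape[0], format="csc")).nnz == 0:
        return M_l
    return spla.splu(M_g).solve(M_l)


def _canonicalize_signs(Z_s: np.ndarray, Z_t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # SVD columns are determined only up to a joint sign; fix it so the
    # largest-magnitude entry of each Z_s column is positive.
    for j in range(Z_s.shape[1]):
        col = Z_s[:, j]
        k = int(np.argmax(np.abs(col)))
        if col[k] < 0:
            Z_s[:, j] = -col
            Z_t[:, j] = -Z_t[:, j]
    return Z_s, Z_t


def hope_embed(
    A: np.ndarray | sp.spmatrix,
    config: ProximityConfig,
    node_order: list[str] | None = None,
) -> NodeEmbedding:
    """Truncated rank-d SVD of the proximity matrix.

    S = U Sigma V^T; Z_s = U_d Sigma_d^{1/2}, Z_t = V_d Sigma_d^{1/2}.
    Columns are sign-canonicalized so the embedding is byte-reproducible.
    """
    n = sp.csr_matrix(A).shape[0]
    if config.dim > n:
        raise ValueError(f"embedding dim {config.dim} exceeds node count {n}")
    S = proximity_matrix(proximity_factors(A, config))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    d = config.dim
    root = np.sqrt(s[:d])
    Z_s = U[:, :d] * root
    Z_t = Vt[:d].T * root
    Z_s, Z_t = _canonicalize_signs(Z_s, Z_t)
    if node_order is None:
        node_order = [str(i) for i in range(n)]
    return NodeEmbedding(Z_s=Z_s, Z_t=Z_t, node_order=list(node_order),
                         config=config, singular_values=s[:d].copy())


def reconstruction_error(S: np.ndarray, Z_s: np.ndarray, Z_t: np.ndarray) -> float:
    """Frobenius norm of S - Z_s Z_t^T (the HOPE objective)."""
    if Z_s.shape != Z_t.shape or S.shape != (Z_s.shape[0], Z_t.shape[0]):
        raise ValueError(
            f"shape mismatch: S {S.shape}, Z_s {Z_s.shape}, Z_t {Z_t.shape}"
        )
    return float(np.linalg.norm(S - Z_s @ Z_t.T, "fro"))


def behavior_feature(embedding: NodeEmbedding, node_id: str) -> np.ndarray:
    """The Z_s row for one node — its network-behavior feature vector."""
    try:
        i = embedding.node_order.index(node_id)
    except ValueError:
        raise KeyError(f"node {node_id!r} not present in embedding") from None
    return embedding.Z_s[i]
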
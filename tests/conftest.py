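import numpy as np
import pytest
from hypothesis import settings

from manlink.man_graph import (
    Association,
    AssociationCategory,
    MoleculeType,
    Node,
    build_man,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def mk(type_char: str, n: int) -> Node:
    t = {
        "m": MoleculeType.MIRNA,
        "l": MoleculeType.LNCRNA,
        "p": MoleculeType.PROTEIN,
        "g": MoleculeType.DRUG,
        "d": MoleculeType.DISEASE,
    }[type_char]
    return Node(t, f"{type_char}{n}")


def edge(a: Node, b: Node) -> Association:
    from manlink.man_graph import category_for_types

    return Association(a, b, category_for_types(a.type, b.type))


@pytest.fixture
def triangle_graph():
    """miRNA-disease, disease-protein, protein-miRNA triangle."""
    m1, d1, p1 = mk("m", 1), mk("d", 1), mk("p", 1)
    return build_man([edge(m1, d1), edge(d1, p1), edge(p1, m1)])


@pytest.fixture(scope="session")
def planted_cv_reports():
    """Behavior-mode five-fold CV on the planted desk network, seeds 1-3."""
    from manlink.experiments import desk_cross_validate

    return {s: desk_cross_validate(s, "planted", "behavior") for s in (1, 2, 3)}


@pytest.fixture(scope="session")
def er_cv_reports():
    """Behavior-mode five-fold CV on the Erdos-Renyi control, seeds 1-3."""
    from manlink.experiments import desk_cross_validate

    return {s: desk_cross_validate(s, "erdos_renyi", "behavior") for s in (1, 2, 3)}


def random_symmetric_adjacency(rng: np.random.Generator, n: int, p: float = 0.3,
                               ensure_degree: bool = True) -> np.ndarray:
    """Random undirected 0/1 adjacency with no zero-degree rows."""
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, k=1)
    A = A + A.T
    if ensure_degree:
        for i in range(n):
            if A[i].sum() == 0:
                j = (i + 1) % n
                A[i, j] = A[j, i] = 1.0
    return A
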
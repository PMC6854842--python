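"""Association (link) prediction over the molecular network.

Each candidate pair is represented by the concatenation
[behavior_i | attribute_i | behavior_j | attribute_j] with (i, j) in
canonical (type, id) order, and scored by a gradient-boosted decision-tree
classifier. Evaluation is leakage-free five-fold cross-validation: the
held-out positive edges are removed from the graph before the behavior
embedding is computed, so no test information reaches the features.
Negatives are balanced 1:1 and category-matched, drawn from node pairs of
the matching types that are edges nowhere in the full network.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import precision_recall_curve, roc_curve

from .hope import NodeEmbedding, ProximityConfig, hope_embed
from .man_graph import (
    Association,
    AssociationCategory,
    MANGraph,
    Node,
    adjacency_matrix,
    category_for_types,
)

__all__ = [
    "PairSample",
    "MetricSet",
    "CVReport",
    "CVConfig",
    "split_folds",
    "sample_negatives",
    "pair_features",
    "train_classifier",
    "compute_metrics",
    "cross_validate",
    "category_case_study",
    "predict",
    "GBDTClassifier",
]

logger = logging.getLogger(__name__)

FEATURE_MODES = ("behavior", "attribute", "combined")


@dataclass(frozen=True)
class PairSample:
    node_i: Node
    node_j: Node
    category: AssociationCategory
    label: int


@dataclass
class MetricSet:
    acc: float
    sen: float
    spec: float
    prec: float
    mcc: float
    auc: float
    aupr: float
    tp: int
    tn: int
    fp: int
    fn: int
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "acc": self.acc, "sen": self.sen, "spec": self.spec,
            "prec": self.prec, "mcc": self.mcc, "auc": self.auc,
            "aupr": self.aupr, "tp": self.tp, "tn": self.tn,
            "fp": self.fp, "fn": self.fn, "undefined": list(self.undefined),
        }


METRIC_NAMES = ("acc", "sen", "spec", "prec", "mcc", "auc", "aupr")


@dataclass
class CVReport:
    folds: list[MetricSet]
    curves: list[dict[str, np.ndarray]] = field(default_factory=list)

    @property
    def mean(self) -> dict[str, float]:
        return {
            m: float(np.mean([getattr(f, m) for f in self.folds]))
            for m in METRIC_NAMES
        }

    @property
    def std(self) -> dict[str, float]:
        return {
            m: float(np.std([getattr(f, m) for f in self.folds]))
            for m in METRIC_NAMES
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "folds": [f.as_dict() for f in self.folds],
                    "mean": self.mean,
                    "std": self.std,
                },
                fh,
                indent=2,
            )
            fh.write("\n")

    def curves_to_tsv(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for k, c in enumerate(self.curves):
            with open(out_dir / f"fold{k}_roc.tsv", "w", encoding="utf-8") as fh:
                fh.write("#fpr\ttpr\n")
                for x, y in zip(c["fpr"], c["tpr"]):
                    fh.write(f"{x:.6g}\t{y:.6g}\n")
            with open(out_dir / f"fold{k}_pr.tsv", "w", encoding="utf-8") as fh:
                fh.write("#recall\tprecision\n")
                for x, y in zip(c["recall"], c["precision"]):
                    fh.write(f"{x:.6g}\t{y:.6g}\n")


class Classifier(Protocol):
    """Pluggable classifier hook: any fit/score pair works in place of the
    default gradient-boosted trees."""

    def fit(self, rows: np.ndarray, labels: np.ndarray) -> "Classifier": ...
    def score_samples(self, rows: np.ndarray) -> np.ndarray: ...


class GBDTClassifier:
    """Gradient-boosted decision trees.

    Uses histogram-based boosting with 500 rounds of shallow trees —
    following the many-shallow-trees default regime of the mainstream
    GBDT implementations — and no further tuning.
    """

    def __init__(self, seed: int = 0, n_rounds: int = 500):
        self._model = HistGradientBoostingClassifier(
            max_iter=n_rounds, random_state=seed
        )

    def fit(self, rows: np.ndarray, labels: np.ndarray) -> "GBDTClassifier":
        labels = np.asarray(labels)
        if len(np.unique(labels)) < 2:
            raise ValueError("training data contains a single class")
        self._model.fit(rows, labels)
        return self

    def score_samples(self, rows: np.ndarray) -> np.ndarray:
        return self._model.predict_proba(rows)[:, 1]


# ---------------------------------------------------------------------------
# Folds and negatives
# ---------------------------------------------------------------------------


def split_folds(
    edges: Iterable[Association], k: int = 5, seed: int = 0
) -> list[list[Association]]:
    """k disjoint random folds covering all edges, sizes differing by <= 1."""
    edges = sorted(edges, key=lambda a: (a.canonical(), a.category.value))
    if k > len(edges):
        raise ValueError(f"cannot split {len(edges)} edges into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(edges))
    folds: list[list[Association]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(edges[idx])
    return folds


def sample_negatives(
    graph: MANGraph,
    positives: Sequence[Association],
    ratio: float = 1.0,
    seed: int = 0,
    forbidden: set[tuple[Node, Node]] | None = None,
) -> list[PairSample]:
    """Category-matched negative pairs absent from the entire network.

    For each association category, draws ratio x (positive count in that
    category) unordered node pairs of the matching types that are edges
    nowhere in the full graph (nor in ``forbidden``, which lets callers
    exclude negatives already used by another fold). Sampling is uniform
    without replacement.
    """
    rng = np.random.default_rng(seed)
    edge_keys = graph.edge_keys()
    forbidden = set(forbidden or ())
    per_cat: dict[AssociationCategory, int] = {}
    for a in positives:
        per_cat[a.category] = per_cat.get(a.category, 0) + 1

    out: list[PairSample] = []
    for category in sorted(per_cat, key=lambda c: c.value):
        want = int(round(ratio * per_cat[category]))
        ta, tb = category.type_pair
        nodes_a = graph.nodes_of_type(ta)
        nodes_b = graph.nodes_of_type(tb)
        chosen: set[tuple[Node, Node]] = set()
        # rejection sampling; cap guards pathological saturation
        max_tries = 200 * want + 1000
        tries = 0
        while len(chosen) < want and tries < max_tries:
            tries += 1
            u = nodes_a[rng.integers(len(nodes_a))]
            v = nodes_b[rng.integers(len(nodes_b))]
            if u == v:
                continue
            key = tuple(sorted((u, v)))
            if key in edge_keys or key in forbidden or key in chosen:
                continue
            chosen.add(key)  # type: ignore[arg-type]
        if len(chosen) < want:
            raise ValueError(
                f"category {category.value}: only {len(chosen)} of {want} "
                "negative pairs available"
            )
        out.extend(
            PairSample(u, v, category, 0) for u, v in sorted(chosen)
        )
    return out


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def _embedding_lookup(embedding: NodeEmbedding) -> dict[str, np.ndarray]:
    return {nid: embedding.Z_s[i] for i, nid in enumerate(embedding.node_order)}


def pair_features(
    behavior: Mapping[str, np.ndarray],
    attributes: Mapping[str, np.ndarray] | None,
    pair: PairSample,
    mode: str = "combined",
    attr_dim: int = 64,
) -> np.ndarray:
    """Feature row [behavior_i | attribute_i | behavior_j | attribute_j].

    Endpoints are put in canonical (type, id) order so an unordered pair
    always maps to the same row. ``mode`` zeroes the attribute blocks
    ("behavior"), the behavior blocks ("attribute"), or neither
    ("combined"). Nodes missing an attribute entry get a zero block.
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"mode must be one of {FEATURE_MODES}")
    i, j = sorted((pair.node_i, pair.node_j))
    blocks: list[np.ndarray] = []
    for node in (i, j):
        if node.id not in behavior:
            raise KeyError(f"node {node.id!r} missing from behavior embedding")
        beh = np.asarray(behavior[node.id], dtype=float)
        if attributes is not None and node.id in attributes:
            att = np.asarray(attributes[node.id], dtype=float)
        else:
            att = np.zeros(attr_dim)
        if mode == "attribute":
            beh = np.zeros_like(beh)
        if mode == "behavior":
            att = np.zeros_like(att)
        blocks.extend((beh, att))
    return np.concatenate(blocks)


def _feature_matrix(
    behavior: Mapping[str, np.ndarray],
    attributes: Mapping[str, np.ndarray] | None,
    pairs: Sequence[PairSample],
    mode: str,
    attr_dim: int,
) -> np.ndarray:
    return np.vstack(
        [pair_features(behavior, attributes, p, mode, attr_dim) for p in pairs]
    )


def train_classifier(
    rows: np.ndarray, labels: np.ndarray, seed: int = 0,
    classifier: Classifier | None = None,
) -> Classifier:
    """Fit the (default GBDT) classifier; scores are probabilities in [0,1]."""
    model = classifier if classifier is not None else GBDTClassifier(seed=seed)
    return model.fit(np.asarray(rows), np.asarray(labels))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def compute_metrics(
    labels: Sequence[int],
    predicted: Sequence[int] | None,
    scores: Sequence[float],
    threshold: float = 0.5,
) -> MetricSet:
    """Confusion-matrix metrics plus trapezoidal AUC and AUPR.

    ``predicted`` defaults to thresholding the scores at 0.5. Metrics whose
    denominator vanishes are set to 0.0 and named in ``undefined``.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if predicted is None:
        p = (s >= threshold).astype(int)
    else:
        p = np.asarray(predicted, dtype=int)
    if not (len(y) == len(p) == len(s)):
        raise ValueError("labels, predictions, and scores must have equal length")

    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))

    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = ratio(tn + tp, tn + tp + fn + fp, "acc")
    sen = ratio(tp, tp + fn, "sen")
    spec = ratio(tn, tn + fp, "spec")
    prec = ratio(tp, tp + fp, "prec")

    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den == 0:
        undefined.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den)

    if len(np.unique(y)) < 2:
        undefined.extend(("auc", "aupr"))
        auc = aupr = 0.0
    else:
        fpr, tpr, _ = roc_curve(y, s)
        auc = float(np.trapezoid(tpr, fpr))
        precision, recall, _ = precision_recall_curve(y, s)
        # recall is decreasing in sklearn's output; integrate over recall
        aupr = float(-np.trapezoid(precision, recall))

    return MetricSet(
        acc=acc, sen=sen, spec=spec, prec=prec, mcc=float(mcc),
        auc=auc, aupr=aupr, tp=tp, tn=tn, fp=fp, fn=fn,
        undefined=tuple(undefined),
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVConfig:
    mode: str = "combined"
    proximity: ProximityConfig = ProximityConfig()
    n_folds: int = 5
    fold_seed: int = 0
    negative_seed: int = 1
    classifier_seed: int = 2
    negative_ratio: float = 1.0
    attr_dim: int = 64


def _fold_embedding(
    train_graph: MANGraph, config: ProximityConfig
) -> dict[str, np.ndarray]:
    """Behavior features from the training graph only.

    Nodes disconnected by the fold removal keep zero behavior vectors so
    test pairs remain scoreable.
    """
    A = adjacency_matrix(train_graph, sparse=True)
    deg = np.asarray(A.sum(axis=1)).ravel()
    active = np.flatnonzero(deg > 0)
    ids = [train_graph.nodes[i].id for i in active]
    if len(active) < train_graph.n_nodes:
        logger.info(
            "%d node(s) disconnected in this fold; zero behavior vectors",
            train_graph.n_nodes - len(active),
        )
    sub = A[np.ix_(active, active)]
    dim = min(config.dim, len(active))
    emb = hope_embed(sub, ProximityConfig(
        measure=config.measure, beta=config.beta,
        alpha=config.alpha, dim=dim), node_order=ids)
    lookup = {nid: np.zeros(config.dim) for nid in
              (n.id for n in train_graph.nodes)}
    for nid, row in zip(ids, emb.Z_s):
        vec = np.zeros(config.dim)
        vec[: len(row)] = row
        lookup[nid] = vec
    return lookup


def _run_folds(
    graph: MANGraph,
    fold_sets: list[list[Association]],
    config: CVConfig,
    attributes: Mapping[str, np.ndarray] | None,
) -> CVReport:
    all_edges = [a for fold in fold_sets for a in fold]
    # one balanced negative pool, folded in parallel with the positives
    negatives = sample_negatives(
        graph, all_edges, ratio=config.negative_ratio, seed=config.negative_seed
    )
    neg_folds = split_folds_pairs(negatives, len(fold_sets), config.negative_seed)

    report = CVReport(folds=[])
    for k, test_edges in enumerate(fold_sets):
        train_graph = graph.subgraph_without(test_edges)
        # leakage assertion: no held-out edge may reach the embedding graph
        assert not (
            {a.canonical() for a in test_edges} & train_graph.edge_keys()
        ), "held-out edges leaked into the embedding graph"
        behavior = _fold_embedding(train_graph, config.proximity)

        train_pos = [
            PairSample(a.source, a.target, a.category, 1)
            for f, fold in enumerate(fold_sets) if f != k for a in fold
        ]
        test_pos = [
            PairSample(a.source, a.target, a.category, 1) for a in test_edges
        ]
        train_neg = [p for f, fold in enumerate(neg_folds) if f != k for p in fold]
        test_neg = neg_folds[k]

        X_train = _feature_matrix(
            behavior, attributes, train_pos + train_neg, config.mode, config.attr_dim
        )
        y_train = np.array([p.label for p in train_pos + train_neg])
        X_test = _feature_matrix(
            behavior, attributes, test_pos + test_neg, config.mode, config.attr_dim
        )
        y_test = np.array([p.label for p in test_pos + test_neg])

        model = train_classifier(X_train, y_train, seed=config.classifier_seed)
        scores = model.score_samples(X_test)
        metrics = compute_metrics(y_test, None, scores)
        report.folds.append(metrics)
        fpr, tpr, _ = roc_curve(y_test, scores)
        precision, recall, _ = precision_recall_curve(y_test, scores)
        report.curves.append(
            {"fpr": fpr, "tpr": tpr, "precision": precision, "recall": recall}
        )
        logger.info(
            "fold %d: n_train=%d n_test=%d auc=%.4f", k, len(y_train),
            len(y_test), metrics.auc,
        )
    return report


def split_folds_pairs(
    pairs: Sequence[PairSample], k: int, seed: int
) -> list[list[PairSample]]:
    """Random disjoint folds of pre-built pair samples."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    folds: list[list[PairSample]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(pairs[idx])
    return folds


def cross_validate(
    graph: MANGraph,
    config: CVConfig = CVConfig(),
    attributes: Mapping[str, np.ndarray] | None = None,
) -> CVReport:
    """Leakage-free k-fold cross-validation over every edge of the network.

    Per fold, the held-out positives are removed before the behavior
    embedding is recomputed on the remaining graph; the classifier is
    trained on the other folds' positives plus matched negatives and
    evaluated on the held-out edges plus this fold's negatives.
    """
    folds = split_folds(graph.edges, config.n_folds, config.fold_seed)
    return _run_folds(graph, folds, config, attributes)


def category_case_study(
    graph: MANGraph,
    category: AssociationCategory,
    config: CVConfig = CVConfig(),
    attributes: Mapping[str, np.ndarray] | None = None,
) -> CVReport:
    """Five-fold evaluation of one association category only.

    Only the chosen category's edges are folded; all other categories'
    edges remain in the embedding graph in every fold, so the embedding
    sees the full cross-category context minus the held-out test edges.
    """
    cat_edges = [a for a in graph.edges if a.category is category]
    if len(cat_edges) < config.n_folds:
        raise ValueError(
            f"category {category.value} has {len(cat_edges)} edges; "
            f"need >= {config.n_folds}"
        )
    folds = split_folds(cat_edges, config.n_folds, config.fold_seed)
    return _run_folds(graph, folds, config, attributes)


def predict(
    model: Classifier,
    behavior: Mapping[str, np.ndarray],
    attributes: Mapping[str, np.ndarray] | None,
    node_i: Node,
    node_j: Node,
    mode: str = "combined",
    attr_dim: int = 64,
) -> float:
    """Association probability for one (canonical-ordered) molecule pair."""
    category = category_for_types(node_i.type, node_j.type)
    pair = PairSample(node_i, node_j, category, 0)
    row = pair_features(behavior, attributes, pair, mode, attr_dim)
    return float(model.score_samples(row[None, :])[0])
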
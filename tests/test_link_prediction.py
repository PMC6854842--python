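"""Fold construction, negative sampling, pair features, metrics (with
brute-force oracles), classifier contracts, and leakage-free CV wiring."""

import numpy as np
import pytest

from manlink.link_prediction import (
    CVConfig,
    GBDTClassifier,
    PairSample,
    compute_metrics,
    cross_validate,
    pair_features,
    predict,
    sample_negatives,
    split_folds,
    train_classifier,
)
from manlink.hope import ProximityConfig
from manlink.man_graph import (AssociationCategory, MoleculeType, build_man,
    category_for_types)
from manlink.synthetic import SyntheticConfig, generate_man
from .conftest import edge, mk


@pytest.fixture(scope="module")
def small_graph():
    g, _ = generate_man(
        SyntheticConfig(
            n_per_type={t: 10 for t in MoleculeType},
            edge_density=0.2,
            seed=3,
        )
    )
    return g


class TestSplitFolds:
    def test_disjoint_union_and_balance(self, small_graph):
        folds = split_folds(small_graph.edges, 5, seed=0)
        keys = [frozenset(a.canonical() for a in f) for f in folds]
        assert sum(len(f) for f in folds) == small_graph.n_edges
        for i in range(5):
            for j in range(i + 1, 5):
                assert not keys[i] & keys[j]
        sizes = sorted(len(f) for f in folds)
        assert sizes[-1] - sizes[0] <= 1

    def test_deterministic_given_seed(self, small_graph):
        f1 = split_folds(small_graph.edges, 5, seed=9)
        f2 = split_folds(small_graph.edges, 5, seed=9)
        assert [[a.canonical() for a in f] for f in f1] == [
            [a.canonical() for a in f] for f in f2
        ]

    def test_ten_edges_five_pairs(self):
        edges = [edge(mk("m", i), mk("d", i)) for i in range(5)]
        edges += [edge(mk("m", i), mk("d", (i + 1) % 5)) for i in range(5)]
        g = build_man(edges)
        folds = split_folds(g.edges, 5, seed=1)
        assert all(len(f) == 2 for f in folds)

    def test_more_folds_than_edges_rejected(self):
        with pytest.raises(ValueError):
            split_folds([edge(mk("m", 1), mk("d", 1))], 5, 0)


class TestSampleNegatives:
    def test_balanced_counts_overall_and_per_category(self, small_graph):
        negs = sample_negatives(small_graph, small_graph.edges, seed=0)
        assert len(negs) == small_graph.n_edges
        pos_per_cat = {}
        for a in small_graph.edges:
            pos_per_cat[a.category] = pos_per_cat.get(a.category, 0) + 1
        neg_per_cat = {}
        for p in negs:
            neg_per_cat[p.category] = neg_per_cat.get(p.category, 0) + 1
        assert neg_per_cat == pos_per_cat

    def test_negatives_disjoint_from_edge_set(self, small_graph):
        negs = sample_negatives(small_graph, small_graph.edges, seed=1)
        keys = small_graph.edge_keys()
        assert all(
            tuple(sorted((p.node_i, p.node_j))) not in keys for p in negs
        )

    def test_no_duplicates_and_type_match(self, small_graph):
        negs = sample_negatives(small_graph, small_graph.edges, seed=2)
        seen = {tuple(sorted((p.node_i, p.node_j))) for p in negs}
        assert len(seen) == len(negs)
        for p in negs:
            assert category_for_types(p.node_i.type, p.node_j.type) is p.category

    def test_saturated_category_rejected(self):
        # 2x2 bipartite with 3 of 4 pairs present: only 1 negative exists
        edges = [
            edge(mk("m", 1), mk("d", 1)),
            edge(mk("m", 1), mk("d", 2)),
            edge(mk("m", 2), mk("d", 1)),
        ]
        g = build_man(edges)
        with pytest.raises(ValueError, match="negative"):
            sample_negatives(g, g.edges, ratio=2.0, seed=0)


class TestPairFeatures:
    @pytest.fixture()
    def lookup(self):
        rng = np.random.default_rng(0)
        beh = {f"m{i}": rng.normal(size=4) for i in range(3)}
        beh.update({f"d{i}": rng.normal(size=4) for i in range(3)})
        att = {k: rng.normal(size=5) for k in beh}
        return beh, att

    def test_combined_length(self, lookup):
        beh, att = lookup
        p = PairSample(mk("m", 1), mk("d", 1), AssociationCategory.MIRNA_DISEASE, 1)
        row = pair_features(beh, att, p, "combined", attr_dim=5)
        assert len(row) == 2 * (4 + 5)

    def test_unordered_pair_canonicalization(self, lookup):
        beh, att = lookup
        a = PairSample(mk("m", 1), mk("d", 1), AssociationCategory.MIRNA_DISEASE, 1)
        b = PairSample(mk("d", 1), mk("m", 1), AssociationCategory.MIRNA_DISEASE, 1)
        assert (
            pair_features(beh, att, a, "combined", 5)
            == pair_features(beh, att, b, "combined", 5)
        ).all()

    def test_mode_blocks_zeroed(self, lookup):
        beh, att = lookup
        p = PairSample(mk("m", 1), mk("d", 1), AssociationCategory.MIRNA_DISEASE, 1)
        row_b = pair_features(beh, att, p, "behavior", 5)
        assert (row_b[4:9] == 0).all() and (row_b[13:18] == 0).all()
        row_a = pair_features(beh, att, p, "attribute", 5)
        assert (row_a[0:4] == 0).all() and (row_a[9:13] == 0).all()

    def test_missing_attribute_zero_block_missing_behavior_raises(self, lookup):
        beh, _ = lookup
        p = PairSample(mk("m", 1), mk("d", 1), AssociationCategory.MIRNA_DISEASE, 1)
        row = pair_features(beh, None, p, "combined", 5)
        assert (row[4:9] == 0).all()
        with pytest.raises(KeyError):
            pair_features({}, None, p, "combined", 5)


class TestComputeMetrics:
    def test_hand_computed_confusion_metrics(self):
        # TP=3, TN=4, FP=1, FN=2
        labels = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        preds  = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        scores = [0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.4, 0.3, 0.2, 0.1]
        m = compute_metrics(labels, preds, scores)
        assert (m.tp, m.tn, m.fp, m.fn) == (3, 4, 1, 2)
        assert m.acc == pytest.approx(0.7)
        assert m.sen == pytest.approx(0.6)
        assert m.spec == pytest.approx(0.8)
        assert m.prec == pytest.approx(0.75)
        assert m.mcc == pytest.approx(10 / np.sqrt(600))

    def test_perfect_prediction(self):
        labels = [1, 1, 0, 0]
        scores = [0.9, 0.8, 0.2, 0.1]
        m = compute_metrics(labels, None, scores)
        for v in (m.acc, m.sen, m.spec, m.prec, m.mcc, m.auc, m.aupr):
            assert v == pytest.approx(1.0)

    def test_undefined_denominators_flagged(self):
        m = compute_metrics([0, 0], None, [0.1, 0.2])
        assert "sen" in m.undefined and "auc" in m.undefined
        assert m.sen == 0.0

    @pytest.mark.parametrize("seed", range(30))
    def test_against_brute_force_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        s = np.round(rng.random(n), 2)  # rounded scores force ties
        m = compute_metrics(y, None, s)
        tp = sum(1 for yi, si in zip(y, s) if yi == 1 and si >= 0.5)
        tn = sum(1 for yi, si in zip(y, s) if yi == 0 and si < 0.5)
        fp = sum(1 for yi, si in zip(y, s) if yi == 0 and si >= 0.5)
        fn = sum(1 for yi, si in zip(y, s) if yi == 1 and si < 0.5)
        assert (m.tp, m.tn, m.fp, m.fn) == (tp, tn, fp, fn)
        assert m.acc == pytest.approx((tp + tn) / n, abs=1e-12)
        den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if den:
            assert m.mcc == pytest.approx(
                (tp * tn - fp * fn) / np.sqrt(den), abs=1e-12
            )
        # AUC oracle: exhaustive concordant/tied pair counting
        pos = s[y == 1]
        neg = s[y == 0]
        conc = sum(
            1.0 if sp > sn else 0.5 if sp == sn else 0.0
            for sp in pos for sn in neg
        )
        assert m.auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-9)


class TestClassifier:
    def test_separable_data_training_accuracy_one(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-3, 0.3, (50, 4)), rng.normal(3, 0.3, (50, 4))])
        y = np.array([0] * 50 + [1] * 50)
        model = train_classifier(X, y, seed=0)
        s = model.score_samples(X)
        assert ((s >= 0.5).astype(int) == y).all()
        assert ((s >= 0) & (s <= 1)).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 6))
        y = (X[:, 0] > 0).astype(int)
        s1 = train_classifier(X, y, seed=5).score_samples(X)
        s2 = train_classifier(X, y, seed=5).score_samples(X)
        assert (s1 == s2).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            GBDTClassifier().fit(np.ones((5, 2)), np.ones(5))


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def tiny_cv(self, ):
        g, _ = generate_man(
            SyntheticConfig(
                n_per_type={t: 12 for t in MoleculeType},
                edge_density=0.25,
                seed=5,
            )
        )
        cfg = CVConfig(proximity=ProximityConfig(dim=4), attr_dim=4)
        return g, cross_validate(g, cfg)

    def test_five_folds_reported(self, tiny_cv):
        _, report = tiny_cv
        assert len(report.folds) == 5

    def test_mean_matches_fold_recomputation(self, tiny_cv):
        _, report = tiny_cv
        assert report.mean["auc"] == pytest.approx(
            np.mean([f.auc for f in report.folds])
        )
        assert report.mean["acc"] == pytest.approx(
            np.mean([f.acc for f in report.folds])
        )

    def test_counts_cover_test_sets(self, tiny_cv):
        g, report = tiny_cv
        total_pos = sum(f.tp + f.fn for f in report.folds)
        assert total_pos == g.n_edges  # every edge held out exactly once

    def test_report_json_roundtrip(self, tiny_cv, tmp_path):
        _, report = tiny_cv
        report.to_json(tmp_path / "cv.json")
        import json

        data = json.loads((tmp_path / "cv.json").read_text())
        assert len(data["folds"]) == 5
        assert data["mean"]["auc"] == pytest.approx(report.mean["auc"])


class TestPredict:
    @pytest.fixture(scope="class")
    def model_and_lookup(self, small_graph):
        from manlink.link_prediction import _fold_embedding, _feature_matrix

        beh = _fold_embedding(small_graph, ProximityConfig(dim=4))
        pos = [PairSample(a.source, a.target, a.category, 1)
               for a in small_graph.edges]
        neg = sample_negatives(small_graph, small_graph.edges, seed=4)
        X = _feature_matrix(beh, None, pos + neg, "behavior", 4)
        y = np.array([p.label for p in pos + neg])
        return train_classifier(X, y, seed=0), beh, small_graph

    def test_score_in_unit_interval_and_symmetric(self, model_and_lookup):
        model, beh, g = model_and_lookup
        ni = g.nodes_of_type(MoleculeType.MIRNA)[0]
        nj = g.nodes_of_type(MoleculeType.DISEASE)[0]
        s_ij = predict(model, beh, None, ni, nj, "behavior", 4)
        s_ji = predict(model, beh, None, nj, ni, "behavior", 4)
        assert 0 <= s_ij <= 1
        assert s_ij == s_ji

    def test_invalid_type_pair_lists_legal_categories(self, model_and_lookup):
        model, beh, g = model_and_lookup
        mt = MoleculeType
        ni = g.nodes_of_type(mt.MIRNA)[0]
        nj = g.nodes_of_type(mt.DRUG)[0]
        with pytest.raises(ValueError, match="legal categories"):
            predict(model, beh, None, ni, nj, "behavior", 4)

    def test_true_edges_score_above_non_edges(self, model_and_lookup):
        model, beh, g = model_and_lookup
        pos = [PairSample(a.source, a.target, a.category, 1) for a in g.edges]
        neg = sample_negatives(g, g.edges, seed=11)
        pos_mean = np.mean([
            predict(model, beh, None, p.node_i, p.node_j, "behavior", 4)
            for p in pos[:60]
        ])
        neg_mean = np.mean([
            predict(model, beh, None, p.node_i, p.node_j, "behavior", 4)
            for p in neg[:60]
        ])
        assert pos_mean > neg_mean
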
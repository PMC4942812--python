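import numpy as np
import pandas as pd
import pytest

import _oracles as oracles
from metcouple import association, classifier
from metcouple.classifier import (
    FEATURE_COLUMNS, RGMClassifier, build_features, build_labels,
    confidence_significance, cross_validate, encode_features,
    permutation_null_confidences, predict_confidences,
)
from metcouple.network import CYTOSOL, connected_gm_pairs, enumerate_rgm_triplets
from metcouple.synthetic import CANCER, NONCANCEROUS, generate_omics

from conftest import stratum_matrices


def _separable_data(n=40, seed=0):
    """Labels determined, with a clear margin, by one continuous feature."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 14))
    y = np.r_[np.ones(n // 2), -np.ones(n - n // 2)].astype(int)
    rng.shuffle(y)
    X[:, 2] = y * rng.uniform(0.5, 2.0, size=n)
    return X, y


class TestFeatures:
    def test_constant_gene_summaries(self, toy_network):
        expr = pd.DataFrame([[5.0] * 4, [1, 2, 3, 4], [0, 0, 1, 1]],
                            index=["g1", "g2", "g3"], columns=list("abcd"),
                            dtype=float)
        trips = enumerate_rgm_triplets(toy_network)
        feats, excluded = build_features(toy_network, expr, trips)
        assert not excluded
        g1 = feats[feats.gene_id == "g1"].iloc[0]
        assert (g1["gene_mean"], g1["gene_var"], g1["gene_min"],
                g1["gene_max"]) == (5.0, 0.0, 5.0, 5.0)

    def test_reaction_counts(self, toy_network):
        expr = pd.DataFrame(np.ones((3, 4)), index=["g1", "g2", "g3"],
                            columns=list("abcd"))
        feats, _ = build_features(toy_network, expr,
                                  enumerate_rgm_triplets(toy_network))
        r2 = feats[feats.reaction_id == "R2"].iloc[0]
        assert (r2["n_substrates"], r2["n_products"], r2["n_metabolites"]) \
            == (2, 1, 3)

    def test_unmeasured_gene_excluded(self, toy_network):
        expr = pd.DataFrame(np.ones((2, 4)), index=["g1", "g2"],
                            columns=list("abcd"))
        feats, excluded = build_features(toy_network, expr,
                                         enumerate_rgm_triplets(toy_network))
        assert all(t.gene_id == "g3" for t in excluded)
        assert "g3" not in set(feats.gene_id)

    def test_matrix_matches_brute_force_recomputation(self, medium_network):
        rng = np.random.default_rng(4)
        genes = sorted(medium_network.genes)
        expr = pd.DataFrame(rng.normal(size=(len(genes), 10)), index=genes,
                            columns=[f"s{i}" for i in range(10)])
        trips = enumerate_rgm_triplets(medium_network)
        feats, _ = build_features(medium_network, expr, trips)
        for i in rng.choice(len(feats), size=15, replace=False):
            row = feats.iloc[i]
            r = medium_network.reactions[row.reaction_id]
            g = expr.loc[row.gene_id]
            expected = [
                r.network_index, r.pathway_id, r.delta_g0, int(r.reversible),
                medium_network.genes[row.gene_id].network_index,
                g.mean(), g.var(ddof=1), g.min(), g.max(),
                medium_network.metabolites[row.metabolite_id].network_index,
                len(r.metabolites), len(r.substrates), len(r.products),
                int(row.is_substrate),
            ]
            assert list(row[FEATURE_COLUMNS]) == pytest.approx(expected)

    def test_onehot_encoding_shape_and_content(self, toy_network):
        expr = pd.DataFrame(np.ones((3, 4)), index=["g1", "g2", "g3"],
                            columns=list("abcd"))
        feats, _ = build_features(toy_network, expr,
                                  enumerate_rgm_triplets(toy_network))
        X = encode_features(feats, toy_network, "onehot")
        n_onehot = (len(toy_network.reactions) + 1) + 2 \
            + (len(toy_network.genes) + 1) + (len(toy_network.metabolites) + 1)
        assert X.shape == (len(feats), 10 + n_onehot)
        raw = encode_features(feats, toy_network, "raw")
        assert raw.shape == (len(feats), 14)


class TestLabels:
    def test_sign_and_threshold_rules(self, toy_network):
        expr = pd.DataFrame(np.ones((3, 4)), index=["g1", "g2", "g3"],
                            columns=list("abcd"))
        feats, _ = build_features(toy_network, expr,
                                  enumerate_rgm_triplets(toy_network))
        tbl = pd.DataFrame([
            ("g1", "a[c]", "all", 0.8, 1e-4, 0.001, 4, False),
            ("g1", "b[c]", "all", -0.6, 1e-3, 0.04, 4, False),
            ("g2", "a[c]", "all", 0.9, 0.1, 0.2, 4, False),
        ], columns=["gene_id", "metabolite_id", "stratum", "rho", "p", "q",
                    "n_samples", "flagged"])
        labels = build_labels(tbl, feats)
        by_pair = dict(zip(zip(feats.gene_id, feats.metabolite_id), labels))
        assert by_pair[("g1", "a[c]")] == 1
        assert by_pair[("g1", "b[c]")] == -1
        assert by_pair[("g2", "a[c]")] == 0      # q above alpha
        assert by_pair[("g3", "a[c]")] == 0      # unmeasured pair


class TestRGMClassifier:
    def test_balancing_subsamples_majority_exactly(self):
        X, y = _separable_data(60, seed=1)
        clf = RGMClassifier(random_state=0).fit(X, y)
        assert clf.n_balanced_ == min((y == 1).sum(), (y == -1).sum())

    def test_separable_training_accuracy(self):
        X, y = _separable_data(40, seed=2)
        clf = RGMClassifier(confidence_mapping="margin",
                            random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 14))
        with pytest.raises(ValueError):
            RGMClassifier().fit(X, np.ones(10, dtype=int))

    @pytest.mark.parametrize("mapping", ["calibrated", "margin"])
    def test_confidence_bounded(self, mapping):
        X, y = _separable_data(30, seed=3)
        clf = RGMClassifier(confidence_mapping=mapping,
                            random_state=0).fit(X, y)
        conf = clf.confidence(np.random.default_rng(1).normal(size=(200, 14)) * 50)
        assert conf.min() >= -1.0 and conf.max() <= 1.0

    def test_feature_dimension_mismatch_rejected(self):
        X, y = _separable_data(30, seed=4)
        clf = RGMClassifier(random_state=0).fit(X, y)
        with pytest.raises(ValueError):
            clf.confidence(X[:, :10])

    def test_sklearn_param_interface(self):
        clf = RGMClassifier(C=2.0, confidence_mapping="margin")
        assert clf.get_params()["C"] == 2.0
        clf.set_params(C=0.5)
        assert clf.C == 0.5


class TestCrossValidation:
    def test_null_labels_give_chance_auc(self):
        rng = np.random.default_rng(7)
        aucs = []
        for seed in range(20):
            X = rng.normal(size=(60, 14))
            y = np.r_[np.ones(30), -np.ones(30)].astype(int)
            rng.shuffle(y)
            aucs.append(cross_validate(X, y, k=5, seed=seed).mean_auc)
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_fold_auc_matches_pair_counting_oracle(self):
        X, y = _separable_data(24, seed=8)
        X += np.random.default_rng(9).normal(size=X.shape)  # imperfect
        cv = cross_validate(X, y, k=4, seed=1)
        for fold in range(4):
            mask = cv.fold_assignments == fold
            y_f, s_f = y[mask], cv.heldout_score[mask]
            if len(np.unique(y_f)) < 2 or mask.sum() > 10:
                continue
            expected = float(oracles.auc_pair_counting(y_f, list(s_f)))
            assert cv.fold_metrics.loc[fold, "auc"] \
                == pytest.approx(expected, abs=1e-12)

    def test_deterministic_under_seed(self):
        X, y = _separable_data(30, seed=10)
        a = cross_validate(X, y, k=5, seed=3)
        b = cross_validate(X, y, k=5, seed=3)
        pd.testing.assert_frame_equal(a.fold_metrics, b.fold_metrics)
        assert np.array_equal(a.heldout_confidence, b.heldout_confidence)

    def test_fewer_labels_than_folds_rejected(self):
        X, y = _separable_data(8, seed=11)
        with pytest.raises(ValueError):
            cross_validate(X, y, k=5, seed=0)

    def test_perfectly_ordered_confidences_give_unit_auc(self):
        # overwhelming single-feature margin: held-out scores order the
        # labels perfectly in every fold
        X, y = _separable_data(40, seed=12)
        X[:, 2] = y * 10.0
        cv = cross_validate(X, y, k=5, seed=0)
        assert cv.mean_auc == pytest.approx(1.0)


@pytest.fixture(scope="module")
def chain(medium_network, medium_cohort):
    cohort, truth = medium_cohort
    pairs = connected_gm_pairs(medium_network, CYTOSOL)
    trips = enumerate_rgm_triplets(medium_network)
    expr, mets = stratum_matrices(cohort, CANCER)
    tbl = association.spearman_table(expr, mets, pairs, stratum="cancer")
    feats, _ = build_features(medium_network, expr, trips)
    labels = build_labels(tbl, feats)
    lab = (labels != 0).to_numpy()
    X_all = encode_features(feats, medium_network)
    return feats, labels, lab, X_all, truth


class TestGenomeWideConfidences:
    def test_unlabeled_rows_do_not_affect_cv(self, chain):
        feats, labels, lab, X_all, _ = chain
        X, y = X_all[lab], labels[lab].to_numpy()
        before = cross_validate(X, y, k=3, seed=5)
        # shuffling unlabeled triplets is irrelevant to cross-validation
        rng = np.random.default_rng(0)
        X_shuf = X_all.copy()
        unl = np.flatnonzero(~lab)
        X_shuf[unl] = X_shuf[rng.permutation(unl)]
        after = cross_validate(X_shuf[lab], labels[lab].to_numpy(), k=3,
                               seed=5)
        pd.testing.assert_frame_equal(before.fold_metrics, after.fold_metrics)

    def test_confidence_table_deterministic(self, chain):
        feats, labels, lab, X_all, _ = chain
        X, y = X_all[lab], labels[lab].to_numpy()
        t1 = predict_confidences(RGMClassifier(random_state=3).fit(X, y),
                                 feats, X_all)
        t2 = predict_confidences(RGMClassifier(random_state=3).fit(X, y),
                                 feats, X_all)
        pd.testing.assert_frame_equal(t1, t2)

    def test_every_triplet_receives_confidence(self, chain):
        feats, labels, lab, X_all, _ = chain
        model = RGMClassifier(random_state=1).fit(X_all[lab],
                                                  labels[lab].to_numpy())
        table = predict_confidences(model, feats, X_all)
        assert len(table) == len(feats)
        assert table["confidence"].between(-1, 1).all()


class TestConfidenceSignificance:
    def test_addone_floor_and_symmetric_null(self):
        rng = np.random.default_rng(13)
        null = rng.normal(scale=0.3, size=999)
        out = confidence_significance([0.0, null.max() + 1.0], null)
        assert out.loc[0, "p"] == pytest.approx(1.0)
        assert out.loc[1, "p"] == pytest.approx(1 / 1000)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            confidence_significance([0.5], [])

    def test_planted_triplets_recovered(self, medium_network, medium_cohort):
        cohort, truth = medium_cohort
        pairs = connected_gm_pairs(medium_network, CYTOSOL)
        trips = enumerate_rgm_triplets(medium_network)
        expr, mets = stratum_matrices(cohort, CANCER)
        tbl = association.spearman_table(expr, mets, pairs, stratum="cancer")
        feats, _ = build_features(medium_network, expr, trips)
        labels = build_labels(tbl, feats)
        lab = (labels != 0).to_numpy()
        X_all = encode_features(feats, medium_network)
        model = RGMClassifier(random_state=0).fit(X_all[lab],
                                                  labels[lab].to_numpy())
        conf = predict_confidences(model, feats, X_all)
        null = permutation_null_confidences(
            X_all[lab], labels[lab].to_numpy(), X_all,
            n_permutations=20, seed=1)
        sig = confidence_significance(conf["confidence"].to_numpy(), null)
        planted = {(cp.gene_id, cp.metabolite_id)
                   for cp in truth.coupled_pairs}
        mask = np.array([(g, m) in planted
                         for g, m in zip(conf.gene_id, conf.metabolite_id)])
        assert mask.sum() >= 10
        assert sig.loc[mask, "significant"].mean() >= 0.7
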
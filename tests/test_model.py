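"""Fisher scores, SVM, cross-validation, metrics, ROC and vote fusion."""

import itertools

import numpy as np
import pytest

from dtibow.model import (
    CVConfig,
    LabeledSignatureSet,
    binary_metrics,
    class_order,
    cross_validate,
    decision_fusion,
    fisher_scores,
    fit_predict_svm_rbf,
    positive_class,
    roc_auc,
)


def fisher_oracle(X, y):
    """Independent loop-based Fisher score: between-class over within-class
    scatter, population class variances, 1e-12 denominator floor."""
    n, p = X.shape
    classes = sorted(set(y))
    out = np.zeros(p)
    for j in range(p):
        mu = sum(X[i, j] for i in range(n)) / n
        between = within = 0.0
        for c in classes:
            vals = [X[i, j] for i in range(n) if y[i] == c]
            nc = len(vals)
            mc = sum(vals) / nc
            between += nc * (mc - mu) ** 2
            within += nc * sum((v - mc) ** 2 for v in vals) / nc
        out[j] = between / max(within, 1e-12)
    return out


class TestFisherScores:
    def test_class_constant_feature_scores_zero(self):
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        y = np.array(["a"] * 4 + ["b"] * 4)
        r = fisher_scores(X, y)
        assert r.scores[0] == 0.0
        assert r.scores[1] > 0

    def test_two_class_example_matches_direct_formula(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0], [10.0], [10.0], [11.0], [11.0]])
        y = np.array(["A"] * 4 + ["B"] * 4)
        r = fisher_scores(X, y)
        assert r.scores[0] == pytest.approx(fisher_oracle(X, y)[0], abs=1e-10)

    def test_translation_invariance(self, rng):
        X = rng.random((20, 5))
        y = np.array(["a", "b"] * 10)
        s1 = fisher_scores(X, y).scores
        s2 = fisher_scores(X + 42.0, y).scores
        np.testing.assert_allclose(s1, s2, atol=1e-8)

    def test_random_problems_match_oracle(self, rng):
        for _ in range(20):
            n_cls = rng.integers(2, 4)
            n, p = int(rng.integers(3 * n_cls, 30)), int(rng.integers(1, 15))
            y = np.repeat([f"c{i}" for i in range(n_cls)], 2)
            y = np.concatenate([y, rng.choice([f"c{i}" for i in range(n_cls)], n - y.size)])
            X = rng.normal(size=(n, p))
            np.testing.assert_allclose(
                fisher_scores(X, y).scores, fisher_oracle(X, y), atol=1e-10
            )

    def test_ranking_sorted_descending_ties_to_lower_index(self):
        X = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [2.0, 2.0, 0.0], [2.0, 2.0, 0.0]])
        y = np.array(["a", "a", "b", "b"])
        r = fisher_scores(X, y)
        assert r.scores[r.order[0]] >= r.scores[r.order[-1]]
        # features 0 and 1 tie; lower index first
        assert list(r.order[:2]) == [0, 1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            fisher_scores(np.ones((4, 2)), np.array(["a"] * 4))


class TestSvm:
    def test_separable_clouds_perfect_accuracy(self, rng):
        X_tr = np.vstack([rng.normal(0, 0.1, (20, 3)), rng.normal(5, 0.1, (20, 3))])
        y_tr = np.array(["NC"] * 20 + ["AD"] * 20)
        X_te = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(5, 0.1, (10, 3))])
        y_te = np.array(["NC"] * 10 + ["AD"] * 10)
        pred, scores, _ = fit_predict_svm_rbf(X_tr, y_tr, X_te, C=10.0, gamma=0.1)
        assert (pred == y_te).all()
        # positive scores favour the more-impaired class (AD)
        assert (scores[y_te == "AD"] > 0).all()
        assert (scores[y_te == "NC"] < 0).all()

    def test_duplicating_training_set_leaves_predictions_unchanged(self, rng):
        # scale-invariance of the empirical problem (separable case: the
        # optimum and hence the decision surface is unchanged)
        X_tr = np.vstack([rng.normal(0, 0.2, (15, 4)), rng.normal(4, 0.2, (15, 4))])
        y_tr = np.array(["NC"] * 15 + ["AD"] * 15)
        X_te = rng.normal(2, 2.0, size=(10, 4))
        p1, _, _ = fit_predict_svm_rbf(X_tr, y_tr, X_te, C=1.0, gamma=0.5)
        p2, _, _ = fit_predict_svm_rbf(
            np.vstack([X_tr, X_tr]), np.concatenate([y_tr, y_tr]), X_te, 1.0, 0.5
        )
        np.testing.assert_array_equal(p1, p2)

    def test_nonfinite_features_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_predict_svm_rbf(X, np.array(["a", "a", "b", "b"]), np.ones((2, 2)), 1, 1)

    def test_permuted_labels_give_chance_level_cv(self, rng):
        # null simulation: features carry no label information
        n = 200
        X = rng.normal(size=(n, 10))
        y = rng.permutation(np.array(["NC", "AD"] * (n // 2)))
        ds = LabeledSignatureSet(X, y)
        rep = cross_validate(ds, k=5, seed=0, config=CVConfig(C=1.0, gamma=0.1))
        # 95% binomial band around 50%
        half_width = 1.96 * np.sqrt(0.25 / n) * 100
        assert abs(rep.accuracy[0] - 50.0) < half_width + 5.0


class TestCrossValidate:
    def _separable(self, rng, n=40):
        X = np.vstack([rng.normal(0, 0.05, (n // 2, 4)), rng.normal(3, 0.05, (n // 2, 4))])
        y = np.array(["NC"] * (n // 2) + ["AD"] * (n // 2))
        return LabeledSignatureSet(X, y)

    def test_separable_cohort_perfect_and_zero_sd(self, rng):
        rep = cross_validate(
            self._separable(rng), k=5, seed=0, config=CVConfig(C=10.0, gamma=0.1)
        )
        assert rep.accuracy == (100.0, 0.0)
        assert rep.auc == pytest.approx(1.0)

    def test_folds_partition_subjects_exactly_once(self, rng):
        ds = self._separable(rng)
        rep = cross_validate(
            ds, k=5, seed=3, config=CVConfig(C=1.0, gamma=0.1, store_artifacts=True)
        )
        idx = np.concatenate([a["test_index"] for a in rep.artifacts])
        assert sorted(idx.tolist()) == list(range(ds.n))

    def test_same_seed_identical_report(self, rng):
        ds = self._separable(rng)
        cfg = CVConfig(C=1.0, gamma=0.1)
        r1 = cross_validate(ds, k=5, seed=9, config=cfg)
        r2 = cross_validate(ds, k=5, seed=9, config=cfg)
        np.testing.assert_array_equal(r1.fold_accuracy, r2.fold_accuracy)
        for c1, c2 in zip(r1.fold_confusions, r2.fold_confusions):
            np.testing.assert_array_equal(c1, c2)

    def test_fold_count_reduced_to_min_class_size(self, rng):
        X = rng.normal(size=(13, 3))
        y = np.array(["NC"] * 10 + ["AD"] * 3)
        with pytest.warns(UserWarning, match="reducing"):
            rep = cross_validate(
                LabeledSignatureSet(X, y), k=10, seed=0, config=CVConfig(C=1, gamma=0.1)
            )
        assert len(rep.fold_confusions) == 3

    def test_k_below_two_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 2"):
            cross_validate(self._separable(rng), k=1)


class TestBinaryMetrics:
    def test_high_sensitivity_low_specificity_pattern(self):
        # TP=5 FN=0 / FP=4 TN=2, positive class second row/col
        conf = np.array([[2, 4], [0, 5]])
        acc, sens, spec = binary_metrics(conf, positive_index=1)
        assert acc == pytest.approx(63.6, abs=0.1)
        assert sens == pytest.approx(100.0)
        assert spec == pytest.approx(33.3, abs=0.1)

    def test_diagonal_matrix_all_100(self):
        assert binary_metrics(np.diag([7, 5])) == (100.0, 100.0, 100.0)

    def test_all_one_class_predictions_degenerate(self):
        conf = np.array([[0, 6], [0, 4]])  # everything predicted positive
        acc, sens, spec = binary_metrics(conf)
        assert sens == 100.0 and spec == 0.0

    def test_empty_margin_undefined_not_zero(self):
        conf = np.array([[3, 1], [0, 0]])  # no true positives at all
        _, sens, spec = binary_metrics(conf)
        assert np.isnan(sens) and spec == 75.0


class TestRocAuc:
    def test_separated_scores_auc_one(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array(["AD", "AD", "NC", "NC"])
        pts, auc = roc_auc(scores, labels)
        assert auc == 1.0
        assert pts[:, 0].min() == 0.0 and pts[:, 1].max() == 1.0

    def test_matches_mann_whitney_pairwise_oracle(self, rng):
        for _ in range(50):
            n_pos, n_neg = rng.integers(3, 30, 2)
            scores = rng.normal(size=n_pos + n_neg)
            labels = np.array(["AD"] * n_pos + ["NC"] * n_neg)
            _, auc = roc_auc(scores, labels)
            pos, neg = scores[:n_pos], scores[n_pos:]
            wins = sum(
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p in pos for q in neg
            )
            assert auc == pytest.approx(wins / (n_pos * n_neg), abs=1e-10)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=100)
        labels = rng.choice(["NC", "AD"], 100)
        if len(set(labels)) < 2:
            labels[0], labels[1] = "NC", "AD"
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.array([1.0, 2.0]), np.array(["AD", "AD"]), positive="AD")


class TestDecisionFusion:
    def test_rd_breaks_two_map_disagreement(self):
        # FA says class 1, MD says class 2 -> RD's vote decides
        assert decision_fusion(2, 1, 2) == 2
        assert decision_fusion(2, 1, 1) == 1

    def test_strict_majority_wins(self):
        assert decision_fusion(1, 1, 2) == 1

    def test_three_way_tie_goes_to_rd(self):
        assert decision_fusion(1, 2, 3) == 3

    def test_all_27_triples_match_majority_with_rd_arbiter(self):
        for md, fa, rd in itertools.product([0, 1, 2], repeat=3):
            votes = [md, fa, rd]
            counts = {v: votes.count(v) for v in set(votes)}
            top = max(counts.values())
            expected = (
                rd if top == 1 else max(counts, key=lambda v: counts[v])
            )
            assert decision_fusion(md, fa, rd) == expected

    def test_missing_vote_rejected(self):
        with pytest.raises(ValueError, match="vote"):
            decision_fusion(1, None, 2)


def test_class_ordering_and_positive_class():
    assert class_order(["AD", "NC", "MCI"]) == ("NC", "MCI", "AD")
    assert positive_class(["NC", "AD"]) == "AD"
    assert positive_class(["MCI", "NC"]) == "MCI"
    with pytest.raises(ValueError):
        positive_class(["NC", "MCI", "AD"])
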
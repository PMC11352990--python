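"""Classification metrics, cross-validation and node-level statistics."""

import numpy as np
import pytest

from cdonbd import (
    FoldScheme,
    SvmParams,
    crossval_classify,
    metrics_from_confusion,
    node_group_stats,
    rank_auc,
)
from cdonbd.exceptions import StratificationError, ValidationError

from oracles import auc_by_pair_counting, bh_stepup


class TestMetricsFromConfusion:
    def test_perfect_classifier(self):
        m = metrics_from_confusion(5, 5, 0, 0)
        assert m.ACC == m.SEN == m.SPE == 1.0

    def test_hand_computed_ratios(self):
        m = metrics_from_confusion(2, 3, 1, 0)
        assert m.ACC == pytest.approx(5 / 6)
        assert m.SEN == 1.0
        assert m.SPE == pytest.approx(0.75)

    def test_zero_denominator_reports_nan(self):
        m = metrics_from_confusion(0, 3, 1, 0)  # no positives at all
        assert np.isnan(m.SEN)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            metrics_from_confusion(-1, 0, 0, 0)


class TestRankAuc:
    def test_all_tied_scores_give_half(self):
        assert rank_auc([0.3] * 6, [1, 1, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_matches_exhaustive_pair_counting(self):
        scores = [0.9, 0.8, 0.4, 0.7, 0.1]
        y = [1, 1, 1, 0, 0]
        assert rank_auc(scores, y) == pytest.approx(auc_by_pair_counting(scores, y))

    def test_pair_counting_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 12))
            scores = rng.choice([0.1, 0.2, 0.5, 0.9], size=n)  # many ties
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            assert rank_auc(scores, y) == pytest.approx(
                auc_by_pair_counting(scores, y), abs=1e-12
            )


class TestCrossvalClassify:
    def _separable(self, rng, per_class=10):
        X = np.vstack(
            [
                rng.normal(loc=0.0, scale=0.1, size=(per_class, 2)),
                rng.normal(loc=5.0, scale=0.1, size=(per_class, 2)),
            ]
        )
        y = np.array(["HC"] * per_class + ["SZ"] * per_class)
        return X, y

    def test_separable_clusters_classified_perfectly(self):
        X, y = self._separable(np.random.default_rng(1))
        m = crossval_classify(X, y, FoldScheme(n_folds=10, seed=0), positive_label="SZ")
        assert m.ACC == 1.0 and m.AUC == 1.0

    def test_shuffled_labels_score_near_chance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 2))
        y = np.array(["HC"] * 30 + ["SZ"] * 30)
        accs = [
            crossval_classify(
                X, rng.permutation(y), FoldScheme(n_folds=10, seed=s), positive_label="SZ"
            ).ACC
            for s in range(5)
        ]
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_pooled_predictions_cover_cohort_exactly_once(self):
        X, y = self._separable(np.random.default_rng(3), per_class=13)
        m = crossval_classify(X, y, FoldScheme(n_folds=5, seed=1), positive_label="SZ")
        assert sum(m.confusion) == 26

    def test_feature_builder_receives_training_indices(self):
        rng = np.random.default_rng(4)
        X, y = self._separable(rng)
        seen = []

        def builder(train_idx):
            seen.append(train_idx.copy())
            return X

        m = crossval_classify(builder, y, FoldScheme(n_folds=5, seed=2), positive_label="SZ")
        assert len(seen) == 5
        for idx in seen:
            assert len(idx) == 16  # 20 subjects, 5 folds -> 4 held out
        assert m.ACC == 1.0

    def test_too_few_subjects_per_class_raises(self):
        X = np.zeros((6, 2))
        y = np.array(["HC", "HC", "HC", "HC", "SZ", "SZ"])
        with pytest.raises(StratificationError):
            crossval_classify(X, y, FoldScheme(n_folds=4, seed=0))

    def test_three_classes_rejected(self):
        X = np.zeros((6, 2))
        y = np.array(["a", "a", "b", "b", "c", "c"])
        with pytest.raises(ValidationError):
            crossval_classify(X, y, FoldScheme(n_folds=2, seed=0))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 2))
        y = np.array(["HC"] * 20 + ["SZ"] * 20)
        scheme = FoldScheme(n_folds=10, seed=9)
        m1 = crossval_classify(X, y, scheme, SvmParams(), positive_label="SZ")
        m2 = crossval_classify(X, y, scheme, SvmParams(), positive_label="SZ")
        assert m1 == m2


class TestNodeGroupStats:
    def test_identical_groups_find_nothing(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(10, 8))
        stats = node_group_stats(A, A.copy())
        assert not stats["significant"].any()

    def test_extreme_shift_detected(self):
        rng = np.random.default_rng(7)
        A = rng.normal(scale=1.0, size=(20, 10))
        B = rng.normal(scale=1.0, size=(20, 10))
        B[:, 3] += 10.0  # ten pooled standard deviations
        stats = node_group_stats(A, B)
        assert stats.loc[3, "significant"]
        assert stats.loc[3, "p_fdr"] < 0.05

    def test_bh_hand_example(self):
        rng = np.random.default_rng(8)
        # construct per-node samples whose Welch p-values we then correct;
        # here we check the correction itself on a fixed p-vector
        p = [0.01, 0.02, 0.04, 0.5]
        expected = bh_stepup(p)
        from statsmodels.stats.multitest import multipletests

        _, got, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_bh_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(9)
        from statsmodels.stats.multitest import multipletests

        for _ in range(1000):
            m = int(rng.integers(1, 21))
            p = rng.random(m)
            _, got, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(got, bh_stepup(p), atol=1e-12)

    def test_zero_variance_node_flagged_with_unit_p(self):
        rng = np.random.default_rng(10)
        A = rng.normal(size=(5, 4))
        B = rng.normal(size=(5, 4))
        A[:, 2] = 1.5
        B[:, 2] = 1.5
        stats = node_group_stats(A, B)
        assert stats.loc[2, "p"] == 1.0
        assert stats.loc[2, "degenerate"]
        assert not stats.loc[2, "significant"]

    def test_neg_log_transform_decreasing_in_p(self):
        rng = np.random.default_rng(11)
        A = rng.normal(size=(8, 12))
        B = rng.normal(size=(8, 12)) + rng.normal(scale=0.5, size=12)
        stats = node_group_stats(A, B).sort_values("p_fdr")
        neg_log = stats["neg_log_p"].to_numpy()
        assert (np.diff(neg_log) <= 1e-12).all()

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            node_group_stats(np.ones((1, 3)), np.ones((4, 3)))
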
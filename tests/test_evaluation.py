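"""PR metrics against independent oracles, the SVM back-end, CV plumbing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import average_precision_score

import episnp as e


def literal_ap(scores, labels):
    """Straight transcription of the recall-increment-weighted AP sum,
    enumerating every distinct score as a cut-off (descending)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    thresholds = sorted(set(scores), reverse=True)
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        pred = scores >= t
        tp = int(((pred == 1) & (labels == 1)).sum())
        fp = int(((pred == 1) & (labels == 0)).sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestPrCurve:
    def test_hand_example_precision(self):
        # threshold admitting 3 cases and 1 control: precision 3/4
        scores = [0.9, 0.8, 0.7, 0.6, 0.1]
        labels = [1, 1, 1, 0, 1]
        curve = e.precision_recall_curve(scores, labels)
        assert curve.precision[3] == pytest.approx(0.75)

    def test_all_predicted_positive_gives_full_recall(self):
        curve = e.precision_recall_curve([0.5, 0.4, 0.3], [0, 1, 1])
        assert curve.recall[-1] == pytest.approx(1.0)

    def test_every_point_matches_confusion_counting(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0] = 1
        curve = e.precision_recall_curve(scores, labels)
        n_pos = labels.sum()
        for t, p, r in zip(curve.thresholds, curve.precision, curve.recall):
            pred = scores >= t
            tp = int((pred & (labels == 1)).sum())
            fp = int((pred & (labels == 0)).sum())
            assert p == pytest.approx(tp / (tp + fp), abs=1e-12)
            assert r == pytest.approx(tp / n_pos, abs=1e-12)

    def test_tied_scores_share_a_threshold(self):
        curve = e.precision_recall_curve([0.5, 0.5, 0.1], [1, 0, 0])
        assert len(curve.thresholds) == 2

    def test_no_positives_is_error(self):
        with pytest.raises(ValueError, match="positive"):
            e.precision_recall_curve([0.1, 0.2], [0, 0])


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert e.average_precision_from_scores([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_worst_two_sample_ranking(self):
        # cut-off 0.9: TP=0,FP=1; cut-off 0.1: TP=1,FP=1 -> AP = 1*0.5
        assert e.average_precision_from_scores([0.1, 0.9], [1, 0]) == pytest.approx(0.5)

    def test_constant_scores_give_prevalence(self):
        labels = np.array([1, 0, 0, 1, 0, 0, 0, 1])
        ap = e.average_precision_from_scores(np.ones(8), labels)
        assert ap == pytest.approx(labels.mean())

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_literal_loop_and_sklearn(self, trial):
        rng = np.random.default_rng(trial)
        n = 50
        scores = np.round(rng.normal(size=n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, size=n)
        labels[rng.integers(n)] = 1
        ap = e.average_precision_from_scores(scores, labels)
        assert ap == pytest.approx(literal_ap(scores, labels), abs=1e-12)
        assert ap == pytest.approx(average_precision_score(labels, scores), abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(-5, 5)), min_size=2, max_size=40))
    def test_oracle_equivalence_property(self, pairs):
        labels = np.array([l for l, _ in pairs])
        scores = np.array([s for _, s in pairs], dtype=float)
        if labels.sum() == 0:
            labels[0] = 1
        ap = e.average_precision_from_scores(scores, labels)
        assert ap == pytest.approx(average_precision_score(labels, scores), abs=1e-9)
        assert 0.0 < ap <= 1.0


class TestAggregates:
    def test_map_single_split(self):
        assert e.mean_average_precision([0.7]) == (pytest.approx(0.7), 0.0)

    def test_map_mean_and_sd(self):
        m, sd = e.mean_average_precision([0.6, 0.8])
        assert m == pytest.approx(0.7)
        assert sd == pytest.approx(np.std([0.6, 0.8], ddof=1))

    def test_map_empty_is_error(self):
        with pytest.raises(ValueError):
            e.mean_average_precision([])

    def test_accuracy_counting(self):
        assert e.overall_accuracy([1, 1, 0, 0], [1, 1, 0, 0]) == 100.0
        assert e.overall_accuracy([1, 0], [0, 0]) == 50.0
        rng = np.random.default_rng(1)
        pred = rng.integers(0, 2, 37)
        y = rng.integers(0, 2, 37)
        assert e.overall_accuracy(pred, y) == pytest.approx(
            100.0 * sum(int(a == b) for a, b in zip(pred, y)) / 37
        )


class TestSvm:
    def test_linear_kernel_is_dot_product(self):
        # the SVM's linear kernel: k(x, y) = x . y
        x, y = np.array([1, 0, 2]), np.array([2, 1, 0])
        assert float(x @ y) == 2.0

    def test_separable_toy_reaches_perfect_ap(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, size=(40, 5)).astype(float)
        y = (X[:, 0] >= 1).astype(int)
        scores = e.svm_train_predict(X[:30], y[:30], X[30:])
        assert e.average_precision_from_scores(scores, y[30:]) == 1.0

    def test_duplicate_training_sample_leaves_scores_unchanged(self):
        X = np.array([[0.0], [0.0], [2.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        test = np.array([[0.5], [1.5]])
        base = e.svm_train_predict(X, y, test)
        dup = e.svm_train_predict(np.vstack([X, X[:1]]), np.r_[y, y[0]], test)
        np.testing.assert_allclose(base, dup, atol=1e-8)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError, match="both classes"):
            e.svm_train_predict(np.zeros((4, 2)), [1, 1, 1, 1], np.zeros((1, 2)))


class TestNestedCv:
    def test_partition_properties_and_leakage(self, toy):
        matrix, pheno, _ = toy
        scheme = e.CvScheme(n_repetitions=2, seed=3)
        spec = e.MethodSpec(name="prs", weights=e.weights_from_truth(toy[2]))
        results = e.repeated_nested_cv(matrix, pheno, scheme, spec)
        assert len(results) == 2 * 5
        e.check_no_leakage(results)
        for rep in range(2):
            tests = [set(r.test_ids) for r in results if r.repetition == rep]
            assert set().union(*tests) == set(matrix.sample_ids)
            for a in range(len(tests)):
                for b in range(a + 1, len(tests)):
                    assert not tests[a] & tests[b]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            e.MethodSpec(name="mystery")


class TestErSubtype:
    def test_planted_er_snps_survive_and_null_is_chance(self, toy):
        matrix, pheno, truth = toy
        er_ids = [s for s, _ in truth.er_snps]
        union = list(er_ids) + [s for s in matrix.snp_ids[:40] if s not in er_ids]
        out = e.er_subtype_task(
            matrix, pheno, union, k_grid=[5, len(union)], seed=0,
            boosting_params=e.BoostingParams(n_trees=100, tree_depth=3, learning_rate=0.1, seed=0),
        )
        # with strong planted ER effects the task is far better than chance
        best = max(v["map"] for v in out.values())
        pos_prev = None
        sub = pheno.for_samples(matrix.sample_ids)
        cases = sub.status == 1
        pos_prev = (sub.er_status[cases] == "positive").mean()
        assert best > pos_prev + 0.1

    def test_requires_both_er_classes(self, small_matrix, small_pheno):
        with pytest.raises(ValueError, match="ER"):
            e.er_subtype_task(small_matrix, small_pheno, list(small_matrix.snp_ids), [2])
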
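"""Split protocol, learner evaluation and the pattern-score aggregation."""

import math

import numpy as np
import pytest

from derga import (
    ALGORITHMS,
    CohortTable,
    ScoreCache,
    SplitProtocol,
    compute_metrics,
    generate_cohort,
    make_splits,
    score_pattern,
    train_and_evaluate,
)
from derga.engine import EvaluationError, make_learner


class TestSplits:
    def test_study_sized_cohort_splits_451_113(self):
        labels = np.r_[np.zeros(300), np.ones(200), np.full(64, 2)]
        splits = make_splits(564, labels, SplitProtocol(n_splits=2, n_seeds=1))
        for s in splits:
            assert len(s.train_indices) == 451
            assert len(s.test_indices) == 113

    def test_floor_rule_small_n(self):
        labels = np.r_[np.zeros(5), np.ones(5)]
        (s,) = make_splits(10, labels, SplitProtocol(n_splits=1, n_seeds=1))
        assert len(s.train_indices) == 8
        assert len(s.test_indices) == 2

    def test_splits_are_deterministic(self):
        labels = np.r_[np.zeros(40), np.ones(40), np.full(20, 2)]
        proto = SplitProtocol(n_splits=3, n_seeds=1, master_seed=5)
        a = make_splits(100, labels, proto)
        b = make_splits(100, labels, proto)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.train_indices, y.train_indices)

    def test_splits_are_disjoint_and_exhaustive(self):
        labels = np.r_[np.zeros(40), np.ones(40), np.full(20, 2)]
        for s in make_splits(100, labels, SplitProtocol(n_splits=4, n_seeds=1)):
            merged = np.sort(np.r_[s.train_indices, s.test_indices])
            np.testing.assert_array_equal(merged, np.arange(100))

    def test_stratified_proportions_within_one_record(self):
        labels = np.r_[np.zeros(50), np.ones(30), np.full(20, 2)]
        (s,) = make_splits(100, labels, SplitProtocol(n_splits=1, n_seeds=1))
        train = labels[s.train_indices]
        for c, share in ((0, 0.5), (1, 0.3), (2, 0.2)):
            assert abs((train == c).sum() - share * len(train)) <= 1


class TestMetrics:
    def test_accuracy_equals_confusion_trace(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 3, 200)
        p = rng.integers(0, 3, 200)
        m = compute_metrics(y, p)
        assert m.accuracy == pytest.approx(m.confusion.trace() / m.confusion.sum())

    def test_macro_values_are_unweighted_class_means(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 3, 200)
        p = rng.integers(0, 3, 200)
        m = compute_metrics(y, p)
        assert m.f1 == pytest.approx(np.mean([c["f1"] for c in m.per_class]))
        assert m.recall == pytest.approx(np.mean([c["recall"] for c in m.per_class]))

    def test_macro_f1_invariant_under_label_permutation(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 3, 300)
        p = rng.integers(0, 3, 300)
        perm = np.array([2, 0, 1])
        a = compute_metrics(y, p)
        b = compute_metrics(perm[y], perm[p])
        assert a.f1 == pytest.approx(b.f1)
        assert a.accuracy == pytest.approx(b.accuracy)

    def test_per_class_f1_is_harmonic_mean(self):
        y = np.array([0, 0, 1, 1, 2, 2, 0, 1])
        p = np.array([0, 1, 1, 1, 2, 0, 0, 2])
        m = compute_metrics(y, p)
        for c in m.per_class:
            pr, rc = c["precision"], c["recall"]
            expect = 0.0 if pr + rc == 0 else 2 * pr * rc / (pr + rc)
            assert c["f1"] == pytest.approx(expect)

    def test_constant_prediction_macro_recall(self):
        y = np.array([0] * 5 + [1] * 3 + [2] * 2)
        p = np.zeros(10, dtype=int)
        m = compute_metrics(y, p)
        recalls = [c["recall"] for c in m.per_class]
        assert recalls == [1.0, 0.0, 0.0]
        assert m.recall == pytest.approx(1 / 3)


class TestTrainAndEvaluate:
    def test_perfectly_separable_pattern_scores_one(self, sep_cohort, one_protocol):
        score = score_pattern("decision_tree", sep_cohort, ["crea_day2"], one_protocol)
        assert score.mean == pytest.approx(1.0)

    def test_identical_inputs_identical_metrics(self, small_cohort, one_protocol):
        splits = make_splits(
            len(small_cohort), small_cohort.outcome_codes, one_protocol
        )
        a = train_and_evaluate("extra_trees", small_cohort, ["age", "crea_day2"], splits[0], 3)
        b = train_and_evaluate("extra_trees", small_cohort, ["age", "crea_day2"], splits[0], 3)
        assert a.metrics.accuracy == b.metrics.accuracy
        np.testing.assert_array_equal(a.metrics.confusion, b.metrics.confusion)

    def test_all_five_algorithms_run(self, small_cohort, one_protocol):
        for alg in ALGORITHMS:
            score = score_pattern(alg, small_cohort, ["crea_day2", "age"], one_protocol)
            assert 0.0 <= score.mean <= 1.0

    def test_degenerate_training_labels_raise(self, small_cohort, one_protocol):
        df = small_cohort.data.copy()
        df["outcome"] = ["alive"] * (len(df) - 1) + ["dead"]
        table = CohortTable(df)
        # the lone "dead" record (last row) is forced into the test partition
        from derga import TrainTestSplit

        n = len(table)
        split = TrainTestSplit(
            train_indices=np.arange(n - 40),
            test_indices=np.arange(n - 40, n),
            split_seed=0,
        )
        with pytest.raises(EvaluationError):
            train_and_evaluate("decision_tree", table, ["age"], split, 0)
        # and the split maker itself refuses partitions missing a class
        from derga.engine import SplitError

        proto = SplitProtocol(n_splits=1, n_seeds=1, stratified=True)
        with pytest.raises(SplitError):
            make_splits(n, table.outcome_codes, proto)

    def test_null_labels_score_majority_share(self):
        # constant feature -> the tree must predict the training majority;
        # expected accuracy is the majority class share
        rng = np.random.default_rng(7)
        accs = []
        p_major = 0.5
        for seed in range(10):
            t = generate_cohort(300, seed=seed)
            df = t.data.copy()
            df["age"] = 47.0
            df["outcome"] = rng.choice(
                ["alive", "dead", "alive_lt24"], p=[0.5, 0.3, 0.2], size=len(df)
            )
            table = CohortTable(df)
            proto = SplitProtocol(n_splits=1, n_seeds=1, master_seed=seed)
            accs.append(score_pattern("decision_tree", table, ["age"], proto).mean)
        n_test_total = 10 * 60
        se = math.sqrt(p_major * (1 - p_major) / n_test_total)
        assert abs(np.mean(accs) - p_major) <= 3 * se


class TestScorePattern:
    def test_evaluation_count_is_grid_product(self, small_cohort):
        proto = SplitProtocol(n_splits=3, n_seeds=2, master_seed=0)
        score = score_pattern("decision_tree", small_cohort, ["age"], proto)
        assert score.n_evaluations == 6

    def test_score_is_pure_function_of_inputs(self, small_cohort, tiny_protocol):
        a = score_pattern("decision_tree", small_cohort, ["age", "crea_day2"], tiny_protocol)
        b = score_pattern("decision_tree", small_cohort, ["age", "crea_day2"], tiny_protocol)
        assert (a.mean, a.sd, a.max) == (b.mean, b.sd, b.max)

    def test_cache_returns_same_object(self, small_cohort, tiny_protocol):
        cache = ScoreCache()
        a = score_pattern(
            "decision_tree", small_cohort, ["age"], tiny_protocol, cache=cache
        )
        b = score_pattern(
            "decision_tree", small_cohort, ["age"], tiny_protocol, cache=cache
        )
        assert a is b
        assert len(cache) == 1

    def test_best_evaluation_attains_max(self, small_cohort, tiny_protocol):
        score = score_pattern("decision_tree", small_cohort, ["age", "agvhd"], tiny_protocol)
        assert score.best.metrics.accuracy == pytest.approx(score.max)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            make_learner("random_forest", 0)
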
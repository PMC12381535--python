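"""Pattern accounting, the greedy elimination loop, selection and ranking."""

from itertools import chain, combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from derga import (
    DergaStep,
    DergaTrajectory,
    MetricsReport,
    ModelEvaluation,
    PatternScore,
    SplitProtocol,
    count_derga_patterns,
    count_exhaustive_patterns,
    count_trained_models,
    rank_parameters,
    run_derga,
    run_ensemble,
    select_optimal,
)

from conftest import threshold_cohort


def nonempty_subsets(items):
    return chain.from_iterable(
        combinations(items, k) for k in range(1, len(items) + 1)
    )


def fake_score(acc: float) -> PatternScore:
    ev = ModelEvaluation(
        algorithm="decision_tree",
        pattern=("x",),
        split_seed=0,
        model_seed=0,
        metrics=MetricsReport(
            accuracy=acc, precision=acc, recall=acc, f1=acc,
            per_class=({}, {}, {}), confusion=np.zeros((3, 3), dtype=int),
        ),
    )
    return PatternScore(mean=acc, sd=0.0, max=acc, n_evaluations=1, best=ev)


def fake_trajectory(per_step_acc):
    """Trajectory over features (a, b, c, ...) with given scored accuracies.

    ``per_step_acc[0]`` is the baseline; each later value is the outgoing
    pattern's score after eliminating the last remaining letter.
    """
    n = len(per_step_acc)
    feats = tuple("abcdefghij"[:n])
    steps = []
    pattern = feats
    for i, acc in enumerate(per_step_acc[1:]):
        eliminated = pattern[-1]
        outgoing = pattern[:-1]
        cands = {f: fake_score(acc if f == eliminated else 0.0) for f in pattern}
        steps.append(
            DergaStep(
                step_index=i,
                incoming_pattern=pattern,
                candidate_scores=cands,
                eliminated_feature=eliminated,
                outgoing_pattern=outgoing,
            )
        )
        pattern = outgoing
    return DergaTrajectory(
        algorithm="decision_tree",
        baseline_pattern=feats,
        baseline_score=fake_score(per_step_acc[0]),
        steps=tuple(steps),
    )


class TestCounts:
    @pytest.mark.parametrize("n, expect", [(1, 2), (2, 6), (18, 524_286)])
    def test_exhaustive_closed_form(self, n, expect):
        assert count_exhaustive_patterns(n) == expect

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6])
    def test_exhaustive_matches_doubled_subset_enumeration(self, n):
        subsets = list(nonempty_subsets(range(n)))
        assert count_exhaustive_patterns(n) == 2 * len(subsets)

    @pytest.mark.parametrize("n, expect", [(1, 1), (4, 10), (18, 171)])
    def test_greedy_pattern_count(self, n, expect):
        assert count_derga_patterns(n) == expect

    def test_study_scale_model_totals(self):
        proto = SplitProtocol(n_splits=25, n_seeds=101)
        assert count_trained_models(18, proto) == 431_775
        assert 5 * count_trained_models(18, proto) == 2_158_875
        assert count_trained_models(1, SplitProtocol(n_splits=1, n_seeds=1)) == 1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n=st.integers(1, 40), splits=st.integers(1, 50), seeds=st.integers(1, 200))
    def test_model_count_scale_equivariance(self, n, splits, seeds):
        proto = SplitProtocol(n_splits=splits, n_seeds=seeds)
        assert count_trained_models(n, proto) == count_derga_patterns(n) * splits * seeds

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            count_exhaustive_patterns(0)
        with pytest.raises(ValueError):
            count_derga_patterns(0)


THREE_FEATURES = ("gender", "age", "crea_day2")  # outcome depends on crea_day2 only


@pytest.fixture(scope="module")
def trajectory(sep_cohort, tiny_protocol):
    return run_derga(sep_cohort, "decision_tree", tiny_protocol, features=THREE_FEATURES)


class TestRunDerga:
    FEATURES = THREE_FEATURES

    def test_noise_free_run_keeps_the_informative_feature(self, trajectory):
        assert trajectory.final_pattern == ("crea_day2",)
        assert set(trajectory.elimination_order) == {"gender", "age"}
        opt = select_optimal(trajectory)
        assert opt.score.statistic("mean") == pytest.approx(1.0)

    def test_trajectory_arithmetic(self, trajectory):
        assert len(trajectory.steps) == len(self.FEATURES) - 1
        assert trajectory.n_patterns_scored == count_derga_patterns(len(self.FEATURES))

    def test_patterns_strictly_nested(self, trajectory):
        pattern = trajectory.baseline_pattern
        for step in trajectory.steps:
            assert step.incoming_pattern == pattern
            assert set(step.outgoing_pattern) < set(step.incoming_pattern)
            pattern = step.outgoing_pattern

    def test_literal_elimination_removes_the_informative_feature_first(
        self, sep_cohort, tiny_protocol
    ):
        traj = run_derga(
            sep_cohort,
            "decision_tree",
            tiny_protocol,
            features=self.FEATURES,
            elimination="literal",
        )
        assert traj.elimination_order[0] == "crea_day2"

    def test_stop_at_bounds_the_run(self, sep_cohort, one_protocol):
        traj = run_derga(
            sep_cohort, "decision_tree", one_protocol,
            features=self.FEATURES, stop_at=2,
        )
        assert len(traj.final_pattern) == 2
        with pytest.raises(ValueError):
            run_derga(sep_cohort, "decision_tree", one_protocol,
                      features=self.FEATURES, stop_at=0)

    def test_determinism(self, sep_cohort, tiny_protocol, trajectory):
        again = run_derga(
            sep_cohort, "decision_tree", tiny_protocol, features=self.FEATURES
        )
        assert again.elimination_order == trajectory.elimination_order
        assert again.baseline_score.mean == trajectory.baseline_score.mean


class TestSelectOptimal:
    def test_argmax_over_scored_patterns(self):
        traj = fake_trajectory([0.80, 0.85, 0.93, 0.90])
        opt = select_optimal(traj)
        assert opt.pattern == ("a", "b")  # the third scored pattern
        assert opt.score.mean == pytest.approx(0.93)

    def test_all_equal_scores_pick_smallest_pattern(self):
        traj = fake_trajectory([0.7, 0.7, 0.7, 0.7])
        assert select_optimal(traj).pattern == ("a",)

    def test_optimal_never_below_baseline(self):
        traj = fake_trajectory([0.9, 0.2, 0.1, 0.05])
        opt = select_optimal(traj)
        assert opt.score.mean >= traj.baseline_score.mean


class TestRankParameters:
    def test_reverse_elimination_order_below_optimal(self):
        # optimal pattern (a,); c eliminated first, then b -> ranking a, b, c
        traj = fake_trajectory([0.5, 0.6, 0.9])
        # steps eliminate c then b (fake_trajectory eliminates from the end)
        opt = select_optimal(traj)
        assert opt.pattern == ("a",)
        ranking = rank_parameters(traj, opt)
        assert ranking == ("a", "b", "c")

    def test_ranking_is_a_permutation_of_all_features(
        self, sep_cohort, tiny_protocol
    ):
        feats = ("gender", "age", "crea_day2", "cgvhd")
        traj = run_derga(sep_cohort, "decision_tree", tiny_protocol, features=feats)
        opt = select_optimal(traj)
        ranking = rank_parameters(
            traj, opt, table=sep_cohort, protocol=tiny_protocol
        )
        assert sorted(ranking) == sorted(feats)
        # features inside the optimal pattern all rank above eliminated ones
        k = len(opt.pattern)
        assert set(ranking[:k]) == set(opt.pattern)

    def test_dominant_feature_ranks_first(self, sep_cohort, tiny_protocol):
        feats = ("gender", "age", "crea_day2")
        traj = run_derga(sep_cohort, "decision_tree", tiny_protocol, features=feats)
        opt = select_optimal(traj)
        ranking = rank_parameters(traj, opt, table=sep_cohort, protocol=tiny_protocol)
        assert ranking[0] == "crea_day2"


class TestGreedyVsOracle:
    def test_greedy_never_beats_exhaustive_and_matches_when_noise_free(
        self, tiny_protocol
    ):
        from derga import score_pattern

        cohort = threshold_cohort(n=240, seed=3)
        feats = ("gender", "age", "crea_day2", "cgvhd")
        traj = run_derga(cohort, "decision_tree", tiny_protocol, features=feats)
        greedy_best = select_optimal(traj).score.mean
        oracle = max(
            score_pattern("decision_tree", cohort, list(s), tiny_protocol).mean
            for s in nonempty_subsets(feats)
        )
        assert greedy_best <= oracle + 1e-12
        assert greedy_best == pytest.approx(oracle, abs=1e-9)


class TestEnsemble:
    def test_single_algorithm_ensemble_matches_run_derga(
        self, sep_cohort, one_protocol
    ):
        feats = ("gender", "age", "crea_day2")
        rep = run_ensemble(
            sep_cohort, one_protocol, algorithms=["decision_tree"], features=feats
        )
        traj = run_derga(sep_cohort, "decision_tree", one_protocol, features=feats)
        opt = select_optimal(traj)
        assert rep.winner == "decision_tree"
        assert rep.reports["decision_tree"].pattern == opt.pattern
        assert rep.reports["decision_tree"].score.mean == pytest.approx(opt.score.mean)

    def test_all_algorithms_recover_the_informative_feature(
        self, sep_cohort, one_protocol
    ):
        feats = ("gender", "crea_day2")
        rep = run_ensemble(sep_cohort, one_protocol, features=feats)
        assert not rep.failures
        for alg, r in rep.reports.items():
            assert "crea_day2" in r.pattern, alg

    def test_winner_has_max_selection_statistic(self, sep_cohort, one_protocol):
        rep = run_ensemble(
            sep_cohort, one_protocol,
            algorithms=["decision_tree", "extra_trees"],
            features=("gender", "crea_day2"),
        )
        stats = {a: r.score.mean for a, r in rep.reports.items()}
        assert stats[rep.winner] == max(stats.values())

    def test_empty_algorithm_list_rejected(self, sep_cohort, one_protocol):
        with pytest.raises(ValueError):
            run_ensemble(sep_cohort, one_protocol, algorithms=[])
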
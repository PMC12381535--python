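"""Greedy backward feature elimination (DERGA) and its pattern accounting.

Starting from the full feature pattern, each round scores every
leave-one-out candidate of the current pattern and eliminates the feature
whose *exclusion* leaves the highest selection statistic — i.e. the feature
the model misses least.  Run to a single remaining feature on *n* features,
the procedure scores exactly ``n(n+1)/2`` distinct patterns (the full
pattern, its *n* leave-one-out children, the ``n-1`` children of the chosen
child, and so on), against ``2(2^n - 1)`` for the doubled exhaustive subset
enumeration it replaces.

The optimal pattern is the scored pattern (baseline included) with maximal
selection statistic; features are then ranked by influence: features inside
the optimal pattern by the drop in the statistic when each is excluded at
the optimal step, features outside it by reverse elimination time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .engine import (
    ALGORITHMS,
    ModelEvaluation,
    PatternScore,
    ScoreCache,
    SplitProtocol,
    score_pattern,
)
from .schema import CohortTable

__all__ = [
    "count_exhaustive_patterns",
    "count_derga_patterns",
    "count_trained_models",
    "canonical_pattern",
    "DergaStep",
    "DergaTrajectory",
    "OptimalModelReport",
    "run_derga",
    "select_optimal",
    "rank_parameters",
    "run_ensemble",
    "EnsembleReport",
]


def count_exhaustive_patterns(n: int) -> int:
    """Number of pattern combinations under the doubled exhaustive count.

    Exhaustive wrapper selection over *n* features would examine every
    non-empty subset, ``2^n - 1`` patterns; the conventional accounting
    doubles this to ``2(2^n - 1)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2 * (2**n - 1)


def count_derga_patterns(n: int) -> int:
    """Number of distinct patterns greedy backward elimination scores.

    Running to a single remaining feature scores the full *n*-feature
    pattern plus every leave-one-out candidate of each round:
    ``n(n+1)/2`` patterns (171 for 18 features).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return n * (n + 1) // 2


def count_trained_models(n: int, protocol: SplitProtocol) -> int:
    """Total model fits for one algorithm: patterns x splits x seeds."""
    return count_derga_patterns(n) * protocol.n_splits * protocol.n_seeds


def canonical_pattern(schema, names: Sequence[str]) -> tuple[str, ...]:
    """Order a feature subset canonically (schema order); validate membership."""
    wanted = set(names)
    if not wanted:
        raise ValueError("pattern must be non-empty")
    unknown = wanted - set(schema.feature_names)
    if unknown:
        raise KeyError(f"not in schema: {sorted(unknown)}")
    return tuple(f for f in schema.feature_names if f in wanted)


@dataclass(frozen=True)
class DergaStep:
    """One elimination round."""

    step_index: int
    incoming_pattern: tuple[str, ...]
    candidate_scores: Mapping[str, PatternScore]
    eliminated_feature: str
    outgoing_pattern: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.outgoing_pattern) != set(self.incoming_pattern) - {
            self.eliminated_feature
        }:
            raise ValueError("outgoing pattern must be incoming minus eliminated")
        if len(self.candidate_scores) != len(self.incoming_pattern):
            raise ValueError("one candidate score per incoming feature required")


@dataclass(frozen=True)
class DergaTrajectory:
    """Ordered record of a full greedy elimination run."""

    algorithm: str
    baseline_pattern: tuple[str, ...]
    baseline_score: PatternScore
    steps: tuple[DergaStep, ...]
    selection_statistic: str = "mean"

    def __post_init__(self) -> None:
        pattern = self.baseline_pattern
        seen = set()
        for step in self.steps:
            if step.incoming_pattern != pattern:
                raise ValueError("steps are not strictly nested")
            if step.eliminated_feature in seen:
                raise ValueError("feature eliminated twice")
            seen.add(step.eliminated_feature)
            if len(step.outgoing_pattern) != len(step.incoming_pattern) - 1:
                raise ValueError("pattern size must decrease by exactly 1")
            pattern = step.outgoing_pattern
        if seen | set(pattern) != set(self.baseline_pattern):
            raise ValueError("eliminations plus final pattern must cover the baseline")

    @property
    def elimination_order(self) -> tuple[str, ...]:
        return tuple(s.eliminated_feature for s in self.steps)

    @property
    def final_pattern(self) -> tuple[str, ...]:
        return self.steps[-1].outgoing_pattern if self.steps else self.baseline_pattern

    @property
    def n_patterns_scored(self) -> int:
        """Distinct patterns scored: baseline plus one per candidate."""
        return 1 + sum(len(s.candidate_scores) for s in self.steps)

    def scored_patterns(self) -> list[tuple[tuple[str, ...], PatternScore]]:
        """Baseline and each step's outgoing pattern, with their scores."""
        out = [(self.baseline_pattern, self.baseline_score)]
        for step in self.steps:
            out.append(
                (step.outgoing_pattern, step.candidate_scores[step.eliminated_feature])
            )
        return out

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "selection_statistic": self.selection_statistic,
            "baseline_pattern": list(self.baseline_pattern),
            "baseline_score": self.baseline_score.to_dict(),
            "steps": [
                {
                    "step_index": s.step_index,
                    "incoming_pattern": list(s.incoming_pattern),
                    "eliminated_feature": s.eliminated_feature,
                    "outgoing_pattern": list(s.outgoing_pattern),
                    "candidate_scores": {
                        k: v.to_dict() for k, v in s.candidate_scores.items()
                    },
                }
                for s in self.steps
            ],
        }


@dataclass(frozen=True)
class OptimalModelReport:
    """The trajectory's best pattern, its score and the feature ranking."""

    algorithm: str
    pattern: tuple[str, ...]
    score: PatternScore
    selection_statistic: str
    ranking: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "pattern": list(self.pattern),
            "selection_statistic": self.selection_statistic,
            "score": self.score.to_dict(),
            "ranking": list(self.ranking),
            "rank_method": "loo-drop",
        }


def run_derga(
    table: CohortTable,
    algorithm: str,
    protocol: SplitProtocol,
    hyper: Mapping[str, dict] | None = None,
    stop_at: int = 1,
    features: Sequence[str] | None = None,
    elimination: str = "greedy",
    selection_statistic: str = "mean",
    cache: ScoreCache | None = None,
    evaluation_log: list[ModelEvaluation] | None = None,
) -> DergaTrajectory:
    """Run greedy backward elimination down to ``stop_at`` features.

    ``features`` restricts the starting pattern (defaults to the full
    schema).  ``elimination="greedy"`` removes the feature whose exclusion
    yields the *highest* selection statistic each round (standard backward
    elimination); ``elimination="literal"`` removes the one whose exclusion
    yields the lowest, for auditing the alternative reading of the
    procedure.  Candidate ties break by schema order of the excluded
    feature.
    """
    if stop_at < 1:
        raise ValueError("stop_at must be >= 1")
    if elimination not in ("greedy", "literal"):
        raise ValueError("elimination must be 'greedy' or 'literal'")
    table.check_trainable()
    pattern = canonical_pattern(table.schema, features or table.schema.feature_names)
    if stop_at > len(pattern):
        raise ValueError("stop_at exceeds the starting pattern size")

    def score(p: tuple[str, ...]) -> PatternScore:
        return score_pattern(
            algorithm, table, p, protocol, hyper, cache=cache, evaluation_log=evaluation_log
        )

    baseline_score = score(pattern)
    steps: list[DergaStep] = []
    step_index = 0
    while len(pattern) > stop_at:
        candidates: dict[str, PatternScore] = {}
        for feat in pattern:
            child = tuple(f for f in pattern if f != feat)
            candidates[feat] = score(child)
        sign = 1.0 if elimination == "greedy" else -1.0
        # ties break toward the earliest feature in schema (= pattern) order
        eliminated = max(
            pattern, key=lambda f: (sign * candidates[f].statistic(selection_statistic),
                                    -pattern.index(f))
        )
        outgoing = tuple(f for f in pattern if f != eliminated)
        steps.append(
            DergaStep(
                step_index=step_index,
                incoming_pattern=pattern,
                candidate_scores=candidates,
                eliminated_feature=eliminated,
                outgoing_pattern=outgoing,
            )
        )
        pattern = outgoing
        step_index += 1
    return DergaTrajectory(
        algorithm=algorithm,
        baseline_pattern=canonical_pattern(
            table.schema, features or table.schema.feature_names
        ),
        baseline_score=baseline_score,
        steps=tuple(steps),
        selection_statistic=selection_statistic,
    )


def select_optimal(trajectory: DergaTrajectory) -> OptimalModelReport:
    """Pick the scored pattern with the maximal selection statistic.

    Ties break toward fewer features (later steps), then earlier step; the
    baseline pattern competes on equal footing, so the winner's statistic is
    never below the full model's.
    """
    stat = trajectory.selection_statistic
    best_pattern, best_score = trajectory.baseline_pattern, trajectory.baseline_score
    for pattern, score in trajectory.scored_patterns()[1:]:
        # later entries are strictly smaller patterns, so >= implements the
        # fewer-features tie-break
        if score.statistic(stat) >= best_score.statistic(stat):
            best_pattern, best_score = pattern, score
    return OptimalModelReport(
        algorithm=trajectory.algorithm,
        pattern=best_pattern,
        score=best_score,
        selection_statistic=stat,
    )


def rank_parameters(
    trajectory: DergaTrajectory,
    optimal: OptimalModelReport,
    table: CohortTable | None = None,
    protocol: SplitProtocol | None = None,
    hyper: Mapping[str, dict] | None = None,
    cache: ScoreCache | None = None,
) -> tuple[str, ...]:
    """Rank all features from most to least influential.

    Features inside the optimal pattern rank first, ordered by the drop in
    the selection statistic when each is excluded at the optimal step
    (largest drop = most influential); the leave-one-out scores are reused
    from the trajectory when the optimal step's candidates were already
    scored, and recomputed otherwise.  Features outside the optimal pattern
    follow, in reverse elimination order (last eliminated first).
    """
    stat = trajectory.selection_statistic
    inside = optimal.pattern
    if len(inside) == 1:
        inside_ranked = list(inside)
    else:
        loo: Mapping[str, PatternScore] | None = None
        for step in trajectory.steps:
            if step.incoming_pattern == inside:
                loo = step.candidate_scores
                break
        if loo is None:
            if table is None or protocol is None:
                raise ValueError(
                    "optimal pattern's leave-one-out scores are not in the "
                    "trajectory; pass table and protocol to recompute them"
                )
            loo = {
                feat: score_pattern(
                    trajectory.algorithm,
                    table,
                    tuple(f for f in inside if f != feat),
                    protocol,
                    hyper,
                    cache=cache,
                )
                for feat in inside
            }
        base = optimal.score.statistic(stat)
        # largest drop first; ties break by schema (pattern) order
        inside_ranked = sorted(
            inside,
            key=lambda f: (-(base - loo[f].statistic(stat)), inside.index(f)),
        )
    eliminated_before = [
        f for f in reversed(trajectory.elimination_order) if f not in set(inside)
    ]
    return tuple(inside_ranked) + tuple(eliminated_before)


@dataclass(frozen=True)
class EnsembleReport:
    """Per-algorithm optimal models plus the overall winner."""

    reports: Mapping[str, OptimalModelReport]
    trajectories: Mapping[str, DergaTrajectory]
    failures: Mapping[str, str]
    winner: str

    def to_dict(self) -> dict:
        return {
            "winner": self.winner,
            "reports": {a: r.to_dict() for a, r in self.reports.items()},
            "failures": dict(self.failures),
        }


def run_ensemble(
    table: CohortTable,
    protocol: SplitProtocol,
    hyper: Mapping[str, dict] | None = None,
    algorithms: Sequence[str] = ALGORITHMS,
    stop_at: int = 1,
    features: Sequence[str] | None = None,
    elimination: str = "greedy",
    selection_statistic: str = "mean",
    cache: ScoreCache | None = None,
) -> EnsembleReport:
    """Run the elimination sweep for each algorithm; report the best of each.

    Per-algorithm failures are recorded and the sweep continues with the
    remaining algorithms; it is an error only if every algorithm fails.
    """
    if not algorithms:
        raise ValueError("need at least one algorithm")
    cache = cache or ScoreCache()
    reports: dict[str, OptimalModelReport] = {}
    trajectories: dict[str, DergaTrajectory] = {}
    failures: dict[str, str] = {}
    for alg in algorithms:
        try:
            traj = run_derga(
                table,
                alg,
                protocol,
                hyper,
                stop_at=stop_at,
                features=features,
                elimination=elimination,
                selection_statistic=selection_statistic,
                cache=cache,
            )
            optimal = select_optimal(traj)
            ranking = rank_parameters(
                traj, optimal, table=table, protocol=protocol, hyper=hyper, cache=cache
            )
            reports[alg] = OptimalModelReport(
                algorithm=alg,
                pattern=optimal.pattern,
                score=optimal.score,
                selection_statistic=optimal.selection_statistic,
                ranking=ranking,
            )
            trajectories[alg] = traj
        except Exception as exc:  # noqa: BLE001 — per-algorithm isolation
            failures[alg] = f"{type(exc).__name__}: {exc}"
    if not reports:
        raise RuntimeError(f"all algorithms failed: {failures}")
    winner = max(
        reports,
        key=lambda a: reports[a].score.statistic(reports[a].selection_statistic),
    )
    return EnsembleReport(
        reports=reports, trajectories=trajectories, failures=failures, winner=winner
    )
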
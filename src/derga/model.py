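"""Model/Results interface over the greedy elimination engine.

`DergaModel` is constructed from a cohort (a validated `CohortTable` or a
raw DataFrame via :meth:`DergaModel.from_dataframe`); its :meth:`fit` runs
the backward-elimination sweep for one meta-algorithm and returns a
`DergaResults` carrying the trajectory, the optimal pattern with its score,
the feature ranking, and a `summary()` table.  `DergaEnsemble` does the same
across all five meta-algorithms and reports the overall winner.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import ALGORITHMS, ScoreCache, SplitProtocol
from .greedy import (
    DergaTrajectory,
    EnsembleReport,
    OptimalModelReport,
    rank_parameters,
    run_derga,
    run_ensemble,
    select_optimal,
)
from .schema import CohortTable, FeatureSchema, default_schema

__all__ = ["DergaModel", "DergaResults", "DergaEnsemble", "EnsembleResults"]


class DergaModel:
    """Greedy backward feature-elimination model for one meta-algorithm.

    Parameters
    ----------
    cohort : CohortTable
        Validated cohort of patient records.
    algorithm : str
        One of ``extra_trees``, ``decision_tree``, ``cat_boost``,
        ``gradient_boosting``, ``ada_boost``.
    protocol : SplitProtocol, optional
        Repeated random-split protocol; defaults to 80/20 stratified splits
        with 25 splits x 101 seeds.
    hyper : mapping, optional
        Per-algorithm hyperparameter overrides (merged over the frozen
        defaults).
    features : sequence of str, optional
        Starting pattern; defaults to all schema features.
    selection_statistic : {"mean", "best"}
        Scalar used to compare patterns: mean test accuracy over the grid, or
        the single best evaluation's accuracy.

    Examples
    --------
    >>> from derga import DergaModel, SplitProtocol, generate_cohort
    >>> cohort = generate_cohort(564, seed=7)
    >>> model = DergaModel(cohort, algorithm="extra_trees",
    ...                    protocol=SplitProtocol(n_splits=3, n_seeds=5))
    >>> res = model.fit()
    >>> print(res.summary())                       # doctest: +SKIP
    """

    def __init__(
        self,
        cohort: CohortTable,
        algorithm: str = "extra_trees",
        protocol: SplitProtocol | None = None,
        hyper: Mapping[str, dict] | None = None,
        features: Sequence[str] | None = None,
        elimination: str = "greedy",
        selection_statistic: str = "mean",
    ) -> None:
        if algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        cohort.check_trainable()
        self.cohort = cohort
        self.algorithm = algorithm
        self.protocol = protocol or SplitProtocol()
        self.hyper = hyper
        self.features = tuple(features) if features else cohort.schema.feature_names
        self.elimination = elimination
        self.selection_statistic = selection_statistic
        self.cache = ScoreCache()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        schema: FeatureSchema | None = None,
        provenance: str = "dataframe",
        **kwargs,
    ) -> "DergaModel":
        """Build a model from a raw DataFrame (validated against the schema)."""
        table = CohortTable(data, schema=schema or default_schema(), provenance=provenance)
        return cls(table, **kwargs)

    def fit(self, stop_at: int = 1) -> "DergaResults":
        """Run the elimination sweep down to ``stop_at`` features."""
        trajectory = run_derga(
            self.cohort,
            self.algorithm,
            self.protocol,
            self.hyper,
            stop_at=stop_at,
            features=self.features,
            elimination=self.elimination,
            selection_statistic=self.selection_statistic,
            cache=self.cache,
        )
        optimal = select_optimal(trajectory)
        ranking = rank_parameters(
            trajectory,
            optimal,
            table=self.cohort,
            protocol=self.protocol,
            hyper=self.hyper,
            cache=self.cache,
        )
        return DergaResults(self, trajectory, optimal, ranking)


class DergaResults:
    """Results of a fitted `DergaModel`."""

    def __init__(
        self,
        model: DergaModel,
        trajectory: DergaTrajectory,
        optimal: OptimalModelReport,
        ranking: tuple[str, ...],
    ) -> None:
        self.model = model
        self.trajectory = trajectory
        self.optimal = OptimalModelReport(
            algorithm=optimal.algorithm,
            pattern=optimal.pattern,
            score=optimal.score,
            selection_statistic=optimal.selection_statistic,
            ranking=ranking,
        )
        self.ranking = ranking

    @property
    def optimal_pattern(self) -> tuple[str, ...]:
        return self.optimal.pattern

    @property
    def optimal_score(self) -> float:
        return self.optimal.score.statistic(self.optimal.selection_statistic)

    @property
    def accuracy_path(self) -> pd.DataFrame:
        """Selection statistic per scored step (baseline first)."""
        stat = self.trajectory.selection_statistic
        rows = [
            {
                "n_features": len(pattern),
                "pattern": ", ".join(pattern),
                stat: score.statistic(stat),
                "sd": score.sd,
            }
            for pattern, score in self.trajectory.scored_patterns()
        ]
        return pd.DataFrame(rows)

    def pattern_matrix(self) -> pd.DataFrame:
        """Presence matrix of the scored patterns (one row per step).

        Columns are the baseline features; a bullet marks membership; the
        final column is the selection statistic.
        """
        stat = self.trajectory.selection_statistic
        feats = self.trajectory.baseline_pattern
        rows = []
        for pattern, score in self.trajectory.scored_patterns():
            row = {f: ("•" if f in pattern else "") for f in feats}
            row["accuracy"] = round(score.statistic(stat), 4)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        t = self.trajectory
        stat = t.selection_statistic
        lines = [
            "Greedy Backward Elimination Results",
            "=" * 59,
            f"Algorithm:            {t.algorithm}",
            f"Selection statistic:  {stat} test accuracy",
            f"Protocol:             {self.model.protocol.n_splits} splits x "
            f"{self.model.protocol.n_seeds} seeds "
            f"(train fraction {self.model.protocol.train_fraction})",
            f"Patterns scored:      {t.n_patterns_scored}",
            f"Baseline ({len(t.baseline_pattern)} features) "
            f"{stat} accuracy: {t.baseline_score.statistic(stat):.4f}",
            "-" * 59,
            f"Optimal pattern ({len(self.optimal.pattern)} features), "
            f"{stat} accuracy {self.optimal_score:.4f}, "
            f"best single evaluation {self.optimal.score.max:.4f}:",
        ]
        lines += [f"    {f}" for f in self.optimal.pattern]
        lines.append("-" * 59)
        lines.append("Feature ranking (most -> least influential; rank method: loo-drop):")
        lines += [f"  {i + 1:2d}. {f}" for i, f in enumerate(self.ranking)]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "optimal": self.optimal.to_dict(),
            "trajectory": self.trajectory.to_dict(),
        }


class DergaEnsemble:
    """Elimination sweep across several meta-algorithms.

    Runs :class:`DergaModel`'s procedure per algorithm (sharing the score
    cache) and reports per-algorithm optima plus the overall winner.
    """

    def __init__(
        self,
        cohort: CohortTable,
        algorithms: Sequence[str] = ALGORITHMS,
        protocol: SplitProtocol | None = None,
        hyper: Mapping[str, dict] | None = None,
        features: Sequence[str] | None = None,
        elimination: str = "greedy",
        selection_statistic: str = "mean",
    ) -> None:
        cohort.check_trainable()
        self.cohort = cohort
        self.algorithms = tuple(algorithms)
        self.protocol = protocol or SplitProtocol()
        self.hyper = hyper
        self.features = tuple(features) if features else None
        self.elimination = elimination
        self.selection_statistic = selection_statistic

    def fit(self, stop_at: int = 1) -> "EnsembleResults":
        report = run_ensemble(
            self.cohort,
            self.protocol,
            self.hyper,
            algorithms=self.algorithms,
            stop_at=stop_at,
            features=self.features,
            elimination=self.elimination,
            selection_statistic=self.selection_statistic,
        )
        return EnsembleResults(self, report)


class EnsembleResults:
    """Results of a fitted `DergaEnsemble`."""

    def __init__(self, model: DergaEnsemble, report: EnsembleReport) -> None:
        self.model = model
        self.report = report

    @property
    def winner(self) -> str:
        return self.report.winner

    @property
    def winning_report(self) -> OptimalModelReport:
        return self.report.reports[self.report.winner]

    def best_models(self) -> pd.DataFrame:
        """One row per algorithm: optimal pattern size and scores."""
        rows = []
        for alg, rep in self.report.reports.items():
            rows.append(
                {
                    "algorithm": alg,
                    "n_features": len(rep.pattern),
                    "selection_statistic": rep.selection_statistic,
                    "score": rep.score.statistic(rep.selection_statistic),
                    "best_accuracy": rep.score.max,
                    "pattern": ", ".join(rep.pattern),
                }
            )
        return pd.DataFrame(rows).sort_values("score", ascending=False, ignore_index=True)

    def summary(self) -> str:
        lines = [
            "Ensemble Backward-Elimination Results",
            "=" * 59,
            f"Algorithms: {', '.join(self.report.reports)}",
        ]
        if self.report.failures:
            lines.append(f"Failed: {self.report.failures}")
        df = self.best_models()
        lines.append(df.to_string(index=False, max_colwidth=40))
        win = self.winning_report
        lines += [
            "-" * 59,
            f"Overall winner: {self.winner} "
            f"({len(win.pattern)} features, "
            f"{win.selection_statistic} accuracy "
            f"{win.score.statistic(win.selection_statistic):.4f})",
            "Winner ranking: " + ", ".join(win.ranking),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return self.report.to_dict()
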
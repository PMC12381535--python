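"""Training and evaluation of the five classification meta-algorithms.

Each candidate feature pattern is scored under a repeated random-split
protocol: ``n_splits`` train/test partitions (default 80/20, stratified by
outcome) crossed with ``n_seeds`` model seeds, all derived deterministically
from a master seed.  The selection statistic used to compare patterns is the
mean test accuracy over the grid; the single best evaluation is also
retained, since a "best model" readout is a common alternative.

The five learners:

- ``extra_trees``      : extremely randomised trees (ExtraTreesClassifier)
- ``decision_tree``    : single CART tree
- ``cat_boost``        : histogram gradient boosting with native categorical
                         splits (HistGradientBoostingClassifier with
                         ``categorical_features``)
- ``gradient_boosting``: classical gradient-boosted trees
- ``ada_boost``        : adaptive boosting over decision stumps

Hyperparameters are frozen in :data:`HYPER_DEFAULTS` rather than left to
library defaults, so results are stable across library versions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
)
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .schema import CohortTable, encode

__all__ = [
    "ALGORITHMS",
    "HYPER_DEFAULTS",
    "SplitProtocol",
    "TrainTestSplit",
    "MetricsReport",
    "ModelEvaluation",
    "PatternScore",
    "SplitError",
    "EvaluationError",
    "make_splits",
    "make_learner",
    "compute_metrics",
    "train_and_evaluate",
    "score_pattern",
    "ScoreCache",
]

#: The five meta-algorithm identifiers, in reporting order.
ALGORITHMS: tuple[str, ...] = (
    "extra_trees",
    "decision_tree",
    "cat_boost",
    "gradient_boosting",
    "ada_boost",
)

#: Frozen hyperparameters per algorithm (ensembles use 100 rounds/trees).
HYPER_DEFAULTS: dict[str, dict] = {
    "extra_trees": {"n_estimators": 100, "max_features": "sqrt"},
    "decision_tree": {"criterion": "gini", "max_depth": None},
    "cat_boost": {"max_iter": 100, "learning_rate": 0.1, "max_depth": None},
    "gradient_boosting": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3},
    "ada_boost": {"n_estimators": 100, "learning_rate": 1.0},
}


class SplitError(RuntimeError):
    """A train/test partition is degenerate (e.g. a class missing)."""


class EvaluationError(RuntimeError):
    """A model could not be trained or evaluated."""


@dataclass(frozen=True)
class SplitProtocol:
    """Repeated random-split evaluation protocol.

    ``n_splits`` split seeds crossed with ``n_seeds`` model seeds gives
    ``n_splits * n_seeds`` evaluations per pattern.  Split seeds are
    ``master_seed + i`` and model seeds ``master_seed + j``.
    """

    train_fraction: float = 0.8
    n_splits: int = 25
    n_seeds: int = 101
    stratified: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_splits < 1 or self.n_seeds < 1:
            raise ValueError("n_splits and n_seeds must be >= 1")

    @property
    def n_evaluations(self) -> int:
        return self.n_splits * self.n_seeds

    def train_size(self, n_records: int) -> int:
        size = math.floor(self.train_fraction * n_records)
        if size < 1 or size >= n_records:
            raise ValueError("train_fraction leaves an empty partition")
        return size

    def key(self) -> tuple:
        return (
            self.train_fraction,
            self.n_splits,
            self.n_seeds,
            self.stratified,
            self.master_seed,
        )


@dataclass(frozen=True)
class TrainTestSplit:
    train_indices: np.ndarray
    test_indices: np.ndarray
    split_seed: int

    def __post_init__(self) -> None:
        tr, te = set(self.train_indices.tolist()), set(self.test_indices.tolist())
        if tr & te:
            raise ValueError("train/test indices overlap")


def make_splits(
    n_records: int, labels: Sequence[int], protocol: SplitProtocol
) -> list[TrainTestSplit]:
    """Create the protocol's train/test partitions.

    Train size is ``floor(train_fraction * n_records)`` (564 records at 0.8
    give the canonical 451/113).  Stratified splits keep per-class train
    proportions within one record of the full-table proportions.
    """
    if n_records < 5:
        raise ValueError("need at least 5 records to split")
    labels = np.asarray(labels)
    train_size = protocol.train_size(n_records)
    classes = np.unique(labels)
    splits = []
    for i in range(protocol.n_splits):
        seed = protocol.master_seed + i
        idx = np.arange(n_records)
        try:
            tr, te = train_test_split(
                idx,
                train_size=train_size,
                random_state=seed,
                shuffle=True,
                stratify=labels if protocol.stratified else None,
            )
        except ValueError as exc:  # stratification impossible (tiny class)
            raise SplitError(str(exc)) from exc
        if len(np.unique(labels[tr])) < len(classes):
            raise SplitError(f"class missing from training partition (seed {seed})")
        splits.append(TrainTestSplit(np.sort(tr), np.sort(te), split_seed=seed))
    return splits


def make_learner(
    algorithm: str,
    model_seed: int,
    hyper: Mapping[str, dict] | None = None,
    categorical_mask: Sequence[bool] | None = None,
):
    """Instantiate a learner with frozen hyperparameters and a seed."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    params = dict(HYPER_DEFAULTS[algorithm])
    if hyper and algorithm in hyper:
        params.update(hyper[algorithm])
    if algorithm == "extra_trees":
        return ExtraTreesClassifier(random_state=model_seed, n_jobs=1, **params)
    if algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=model_seed, **params)
    if algorithm == "cat_boost":
        mask = list(categorical_mask) if categorical_mask is not None else None
        return HistGradientBoostingClassifier(
            random_state=model_seed, categorical_features=mask, **params
        )
    if algorithm == "gradient_boosting":
        return GradientBoostingClassifier(random_state=model_seed, **params)
    return AdaBoostClassifier(random_state=model_seed, **params)


@dataclass(frozen=True)
class MetricsReport:
    """Multiclass performance indices on a test partition.

    ``precision``/``recall``/``f1`` are macro averages (unweighted means of
    the three one-vs-rest per-class values); ``confusion`` is the 3x3 count
    matrix with true classes on rows.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: tuple[dict, ...]
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision_macro": self.precision,
            "recall_macro": self.recall,
            "f1_macro": self.f1,
            "per_class": list(self.per_class),
            "confusion": self.confusion.tolist(),
        }


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 3) -> MetricsReport:
    labels = list(range(n_classes))
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    per_class = tuple(
        {"class": c, "precision": float(prec[c]), "recall": float(rec[c]), "f1": float(f1[c])}
        for c in labels
    )
    return MetricsReport(
        accuracy=float(cm.trace() / cm.sum()),
        precision=float(prec.mean()),
        recall=float(rec.mean()),
        f1=float(f1.mean()),
        per_class=per_class,
        confusion=cm,
    )


@dataclass(frozen=True)
class ModelEvaluation:
    algorithm: str
    pattern: tuple[str, ...]
    split_seed: int
    model_seed: int
    metrics: MetricsReport

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "pattern": list(self.pattern),
            "split_seed": self.split_seed,
            "model_seed": self.model_seed,
            "metrics": self.metrics.to_dict(),
        }


def train_and_evaluate(
    algorithm: str,
    table: CohortTable,
    pattern: Sequence[str],
    split: TrainTestSplit,
    model_seed: int,
    hyper: Mapping[str, dict] | None = None,
) -> ModelEvaluation:
    """Fit one learner on the encoded training partition; score on test."""
    table.check_trainable()
    fm = encode(table, pattern)
    y_train = fm.labels[split.train_indices]
    if len(np.unique(y_train)) < 2:
        raise EvaluationError("training partition holds a single outcome class")
    cat_mask = [table.schema[n].kind == "categorical" for n in fm.feature_names]
    learner = make_learner(algorithm, model_seed, hyper, categorical_mask=cat_mask)
    learner.fit(fm.values[split.train_indices], y_train)
    y_pred = learner.predict(fm.values[split.test_indices])
    metrics = compute_metrics(fm.labels[split.test_indices], y_pred)
    return ModelEvaluation(
        algorithm=algorithm,
        pattern=fm.feature_names,
        split_seed=split.split_seed,
        model_seed=model_seed,
        metrics=metrics,
    )


@dataclass(frozen=True)
class PatternScore:
    """Aggregate of test accuracy over the split x seed grid."""

    mean: float
    sd: float
    max: float
    n_evaluations: int
    best: ModelEvaluation

    def statistic(self, which: str = "mean") -> float:
        if which == "mean":
            return self.mean
        if which == "best":
            return self.max
        raise ValueError(f"unknown selection statistic {which!r}")

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "max": self.max,
            "n_evaluations": self.n_evaluations,
            "best": self.best.to_dict(),
        }


class ScoreCache:
    """In-memory memoisation of pattern scores.

    Scoring is a pure function of (table, pattern, algorithm, protocol,
    hyper); the greedy path never revisits a pattern, but ensemble sweeps and
    ranking re-score patterns, so memoisation pays for itself.
    """

    def __init__(self) -> None:
        self._store: dict[tuple, PatternScore] = {}

    @staticmethod
    def _hyper_key(hyper: Mapping[str, dict] | None) -> tuple:
        if not hyper:
            return ()
        return tuple(sorted((a, tuple(sorted(d.items()))) for a, d in hyper.items()))

    def key(self, table, algorithm, pattern, protocol, hyper) -> tuple:
        return (
            id(table),
            algorithm,
            tuple(pattern),
            protocol.key(),
            self._hyper_key(hyper),
        )

    def get(self, key: tuple) -> PatternScore | None:
        return self._store.get(key)

    def put(self, key: tuple, score: PatternScore) -> None:
        self._store[key] = score

    def __len__(self) -> int:
        return len(self._store)


def score_pattern(
    algorithm: str,
    table: CohortTable,
    pattern: Sequence[str],
    protocol: SplitProtocol,
    hyper: Mapping[str, dict] | None = None,
    cache: ScoreCache | None = None,
    evaluation_log: list[ModelEvaluation] | None = None,
) -> PatternScore:
    """Score a pattern over the full split x seed grid.

    Returns the mean, standard deviation and maximum of test accuracy over
    ``protocol.n_splits * protocol.n_seeds`` evaluations, with the single
    best evaluation retained.
    """
    key = None
    if cache is not None:
        key = cache.key(table, algorithm, pattern, protocol, hyper)
        hit = cache.get(key)
        if hit is not None:
            return hit
    splits = make_splits(len(table), table.outcome_codes, protocol)
    accs: list[float] = []
    best: ModelEvaluation | None = None
    for split in splits:
        for j in range(protocol.n_seeds):
            ev = train_and_evaluate(
                algorithm, table, pattern, split, protocol.master_seed + j, hyper
            )
            accs.append(ev.metrics.accuracy)
            if evaluation_log is not None:
                evaluation_log.append(ev)
            if best is None or ev.metrics.accuracy > best.metrics.accuracy:
                best = ev
    arr = np.asarray(accs)
    score = PatternScore(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=0)),
        max=float(arr.max()),
        n_evaluations=len(arr),
        best=best,
    )
    if cache is not None and key is not None:
        cache.put(key, score)
    return score
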
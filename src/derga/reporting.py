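"""Report rendering and end-to-end pipeline orchestration.

Every number in a rendered report is taken from logged scores; the rendering
layer performs no model fitting of its own.  Pipeline runs write their
resolved configuration (with a content hash) next to their artifacts, so
runs from different configurations never overwrite each other.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .engine import ALGORITHMS, SplitProtocol
from .greedy import DergaTrajectory, count_derga_patterns, count_exhaustive_patterns, count_trained_models
from .io import read_cohort, write_cohort
from .model import DergaEnsemble, EnsembleResults
from .schema import CohortTable
from .simulate import CellConstraint, MarginalSpec, SignalSpec, generate_cohort

__all__ = ["RunConfig", "render_pattern_matrix", "render_counts", "run_pipeline"]


def render_pattern_matrix(trajectory: DergaTrajectory) -> str:
    """TSV presence matrix of a trajectory's scored patterns.

    One row per scored step pattern (baseline first); one column per feature
    of the baseline pattern holding a bullet when the feature participates;
    a trailing accuracy column formatted to 4 decimals.
    """
    stat = trajectory.selection_statistic
    feats = trajectory.baseline_pattern
    lines = ["\t".join([*feats, "accuracy"])]
    for pattern, score in trajectory.scored_patterns():
        present = set(pattern)
        cells = ["•" if f in present else "" for f in feats]
        cells.append(f"{score.statistic(stat):.4f}")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def render_counts(n: int, protocol: SplitProtocol, n_algorithms: int = len(ALGORITHMS)) -> str:
    """Plain-text pattern/model accounting for an n-feature database."""
    derga_n = count_derga_patterns(n)
    per_alg = count_trained_models(n, protocol)
    return "\n".join(
        [
            f"features:                     {n}",
            f"exhaustive pattern count:     {count_exhaustive_patterns(n):,}",
            f"greedy pattern count:         {derga_n:,}",
            f"protocol:                     {protocol.n_splits} splits x {protocol.n_seeds} seeds",
            f"models per algorithm:         {per_alg:,}",
            f"models for {n_algorithms} algorithms:       {per_alg * n_algorithms:,}",
        ]
    )


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (YAML round-trippable)."""

    cohort_path: str | None = None
    synthetic_n: int | None = 564
    synthetic_seed: int = 0
    marginals: Mapping | None = None  # MarginalSpec dict; None = defaults
    signal: Mapping | None = None  # SignalSpec dict; None = defaults
    cell_min_count: int | None = None
    protocol: Mapping = field(
        default_factory=lambda: {"train_fraction": 0.8, "n_splits": 3, "n_seeds": 5,
                                 "stratified": True, "master_seed": 0}
    )
    hyper: Mapping | None = None
    algorithms: Sequence[str] = ALGORITHMS
    elimination: str = "greedy"
    selection_statistic: str = "mean"
    stop_at: int = 1
    out_dir: str = "derga_results"

    def to_dict(self) -> dict:
        d = {
            "cohort_path": self.cohort_path,
            "synthetic_n": self.synthetic_n,
            "synthetic_seed": self.synthetic_seed,
            "marginals": dict(self.marginals) if self.marginals else None,
            "signal": dict(self.signal) if self.signal else None,
            "cell_min_count": self.cell_min_count,
            "protocol": dict(self.protocol),
            "hyper": dict(self.hyper) if self.hyper else None,
            "algorithms": list(self.algorithms),
            "elimination": self.elimination,
            "selection_statistic": self.selection_statistic,
            "stop_at": self.stop_at,
            "out_dir": self.out_dir,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {k: d[k] for k in d if k in cls.__dataclass_fields__}
        return cls(**known)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def build_protocol(self) -> SplitProtocol:
        return SplitProtocol(**self.protocol)

    def load_cohort(self) -> CohortTable:
        if self.cohort_path is not None:
            return read_cohort(self.cohort_path)
        marg = MarginalSpec.from_dict(self.marginals) if self.marginals else None
        sig = SignalSpec.from_dict(self.signal) if self.signal else None
        cons = CellConstraint(self.cell_min_count) if self.cell_min_count else None
        return generate_cohort(
            self.synthetic_n, marg, sig, constraint=cons, seed=self.synthetic_seed
        )


def run_pipeline(config: RunConfig) -> EnsembleResults:
    """Load or generate the cohort, run the ensemble sweep, write artifacts.

    Writes under ``<out_dir>/<config-hash>/``: the resolved config, the
    cohort (when synthetic), per-algorithm trajectory and optimal-model JSON,
    a pattern-matrix TSV for each algorithm, a best-models CSV and a
    plain-text summary.  On a stage failure, partial artifacts are kept with
    an ``error.json`` manifest and the exception is re-raised.
    """
    out = Path(config.out_dir) / config.content_hash()
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    try:
        cohort = config.load_cohort()
        if config.cohort_path is None:
            write_cohort(cohort, out / "cohort.csv")
        ensemble = DergaEnsemble(
            cohort,
            algorithms=config.algorithms,
            protocol=config.build_protocol(),
            hyper=config.hyper,
            elimination=config.elimination,
            selection_statistic=config.selection_statistic,
        )
        results = ensemble.fit(stop_at=config.stop_at)
    except Exception as exc:
        (out / "error.json").write_text(
            json.dumps({"error": type(exc).__name__, "message": str(exc)}, indent=2)
        )
        raise
    meta = {
        "config_hash": config.content_hash(),
        "python": platform.python_version(),
    }
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2))
    for alg, traj in results.report.trajectories.items():
        (out / f"trajectory_{alg}.json").write_text(json.dumps(traj.to_dict(), indent=2))
        (out / f"pattern_matrix_{alg}.tsv").write_text(render_pattern_matrix(traj))
    for alg, rep in results.report.reports.items():
        (out / f"optimal_{alg}.json").write_text(json.dumps(rep.to_dict(), indent=2))
    results.best_models().to_csv(out / "best_models.csv", index=False)
    (out / "summary.txt").write_text(results.summary() + "\n")
    return results
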
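"""Cohort data model for allo-HSCT survival-status prediction.

The cohort schema covers 18 pre- and post-transplant parameters recorded for
each allogeneic haematopoietic stem cell transplant (allo-HSCT) recipient,
plus a three-level survivorship outcome (alive / dead / alive but followed
for less than 24 months).  Categorical parameters carry ordinal integer
codes; continuous parameters carry their clinical units and an admissible
range.  Tree learners consume the codes and raw values directly, so no
one-hot expansion or rescaling is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureDef",
    "FeatureSchema",
    "CohortTable",
    "FeatureMatrix",
    "default_schema",
    "encode",
    "FIGURE_ABBREVIATIONS",
    "OUTCOME_LEVELS",
    "OUTCOME_SYNONYMS",
]

#: Fixed outcome labels, in fixed order; integer codes are their positions.
OUTCOME_LEVELS: tuple[str, str, str] = ("alive", "dead", "alive_lt24")

#: Case-insensitive synonyms accepted on read (long clinical phrasings).
OUTCOME_SYNONYMS: dict[str, str] = {
    "alive": "alive",
    "dead": "dead",
    "alive_lt24": "alive_lt24",
    "alive but follow-up less than 24 months": "alive_lt24",
    "alive but follow up less than 24 months": "alive_lt24",
}


class SchemaError(ValueError):
    """A file or table does not conform to the cohort schema."""


class ValidationError(ValueError):
    """A row violates a feature's level set or admissible range."""


@dataclass(frozen=True)
class FeatureDef:
    """Definition of one cohort parameter.

    Parameters
    ----------
    name : str
        Identifier used as the column name in cohort files.
    kind : {"categorical", "continuous"}
    levels : mapping, optional
        For categorical features, label -> integer code.  Codes are
        consecutive integers starting at 0 or 1.
    units : str, optional
        For continuous features, the clinical unit.
    range : tuple, optional
        For continuous features, the admissible (min, max).
    """

    name: str
    kind: str
    levels: Mapping[str, int] | None = None
    units: str | None = None
    range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.levels:
                raise ValueError(f"{self.name}: categorical feature needs levels")
            codes = sorted(self.levels.values())
            if codes[0] not in (0, 1) or codes != list(
                range(codes[0], codes[0] + len(codes))
            ):
                raise ValueError(
                    f"{self.name}: codes must be consecutive integers from 0 or 1"
                )
        else:
            if self.range is None or not self.range[0] < self.range[1]:
                raise ValueError(f"{self.name}: continuous range must have min < max")

    @property
    def codes(self) -> frozenset[int]:
        assert self.levels is not None
        return frozenset(self.levels.values())


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of 18 feature definitions plus the outcome labels."""

    features: tuple[FeatureDef, ...]
    outcome_levels: tuple[str, ...] = OUTCOME_LEVELS

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")
        if tuple(self.outcome_levels) != OUTCOME_LEVELS:
            raise ValueError(f"outcome levels must be {OUTCOME_LEVELS}")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    def __getitem__(self, name: str) -> FeatureDef:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.feature_names

    def __len__(self) -> int:
        return len(self.features)

    def to_json(self) -> str:
        """Machine-readable JSON description of the schema."""
        out = {
            "outcome_levels": list(self.outcome_levels),
            "features": [
                {
                    "name": f.name,
                    "kind": f.kind,
                    **(
                        {"levels": dict(f.levels)}
                        if f.kind == "categorical"
                        else {"units": f.units, "range": list(f.range)}
                    ),
                }
                for f in self.features
            ],
        }
        return json.dumps(out, indent=2)


def default_schema() -> FeatureSchema:
    """The 18-parameter allo-HSCT cohort schema.

    Categorical groupings mirror the cohort's descriptive statistics table
    (numbered disease / donor / DRI groups etc.); continuous parameters keep
    their clinical units and observed ranges.
    """
    f = FeatureDef
    return FeatureSchema(
        features=(
            f("gender", "categorical", levels={"male": 1, "female": 2}),
            f("age", "continuous", units="years", range=(18.0, 88.0)),
            # (1) lymphoid: ALL, HL, NHL, PLL, MPAL; (2) myeloid: AML, MDS,
            # MDS/MPN, MF; (3) other: aplastic anaemia, autoimmune, CLL, CML,
            # MM, plasma cell disorders
            f("disease", "categorical", levels={"lymphoid": 1, "myeloid": 2, "other": 3}),
            f("disease_phase", "categorical", levels={"chemosensitive": 1, "chemoresistant": 2}),
            f("donor_type", "categorical", levels={"sibling": 1, "unrelated": 2, "haploidentical": 3}),
            f("hla_group", "categorical", levels={"matched": 1, "mismatched": 2}),
            f("graft_source", "categorical", levels={"peripheral": 1, "bone_marrow": 2, "other": 3}),
            f("conditioning", "categorical", levels={"myeloablative": 1, "reduced": 2}),
            f("plt_day2", "continuous", units="10^9/L", range=(3.0, 922.2)),
            f("ldh_day2", "continuous", units="mg/dL", range=(14.0, 4326.0)),
            f("crea_day2", "continuous", units="mg/dL", range=(0.6, 5.3)),
            f("cd34", "continuous", units="10^6/kg", range=(1.23, 19.8)),
            f("neut_engraft", "categorical", levels={"no": 0, "yes": 1}),
            f("plt_engraft", "categorical", levels={"no": 0, "yes": 1}),
            f("dri", "categorical", levels={"low": 1, "intermediate": 2, "high": 3}),
            f("agvhd", "categorical", levels={"grade0_or_I": 1, "other": 2}),
            f("cgvhd", "categorical", levels={"no": 0, "yes": 1}),
            f("sec_malig", "categorical", levels={"no": 0, "yes": 1}),
        )
    )


#: Mapping from the abbreviations used in published model summaries to
#: schema feature names (one entry per schema feature).
FIGURE_ABBREVIATIONS: dict[str, str] = {
    "Gender": "gender",
    "Age": "age",
    "Disease": "disease",
    "DF": "disease_phase",
    "DT": "donor_type",
    "HLA": "hla_group",
    "GS": "graft_source",
    "CR": "conditioning",
    "PLT": "plt_day2",
    "LDH": "ldh_day2",
    "Crea": "crea_day2",
    "CD34": "cd34",
    "NEUT": "neut_engraft",
    "PLAT": "plt_engraft",
    "DRI": "dri",
    "aGVHD": "agvhd",
    "cGVHD": "cgvhd",
    "sMAL": "sec_malig",
}


class CohortTable:
    """A validated cohort of patient records.

    Wraps a :class:`pandas.DataFrame` whose columns are the schema features
    (in schema order) plus ``outcome`` (canonical string labels).  Rows with
    missing values, out-of-level categorical codes or out-of-range continuous
    values are rejected at construction.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        schema: FeatureSchema | None = None,
        provenance: str = "unknown",
    ) -> None:
        schema = schema or default_schema()
        self.schema = schema
        self.provenance = provenance
        self.data = self._validate(data, schema)

    @staticmethod
    def _validate(data: pd.DataFrame, schema: FeatureSchema) -> pd.DataFrame:
        missing = [c for c in (*schema.feature_names, "outcome") if c not in data.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        df = data.loc[:, [*schema.feature_names, "outcome"]].reset_index(drop=True)
        if df.isna().any().any():
            rows = df.index[df.isna().any(axis=1)].tolist()
            raise ValidationError(f"missing values in row(s) {rows}")
        # canonicalise outcome labels
        outcomes = (
            df["outcome"].astype(str).str.strip().str.lower().map(OUTCOME_SYNONYMS)
        )
        if outcomes.isna().any():
            bad = df.index[outcomes.isna()].tolist()
            raise ValidationError(f"unrecognised outcome label in row(s) {bad}")
        df["outcome"] = outcomes
        for fdef in schema.features:
            col = df[fdef.name]
            if fdef.kind == "categorical":
                vals = pd.to_numeric(col, errors="coerce")
                ok = vals.isin(list(fdef.codes))
                if not ok.all():
                    bad = df.index[~ok].tolist()
                    raise ValidationError(
                        f"{fdef.name}: value outside level set in row(s) {bad}"
                    )
                df[fdef.name] = vals.astype(np.int64)
            else:
                vals = pd.to_numeric(col, errors="coerce")
                lo, hi = fdef.range
                ok = vals.notna() & (vals >= lo) & (vals <= hi)
                if not ok.all():
                    bad = df.index[~ok].tolist()
                    raise ValidationError(
                        f"{fdef.name}: value outside [{lo}, {hi}] in row(s) {bad}"
                    )
                # canonical precision: 6 significant digits, so CSV round
                # trips are exact identities
                df[fdef.name] = np.array(
                    [float(format(v, ".6g")) for v in vals], dtype=np.float64
                )
        return df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def outcome_codes(self) -> np.ndarray:
        """Integer-coded outcomes: alive -> 0, dead -> 1, alive_lt24 -> 2."""
        lut = {lab: i for i, lab in enumerate(self.schema.outcome_levels)}
        return self.data["outcome"].map(lut).to_numpy(dtype=np.int64)

    def check_trainable(self) -> None:
        """Raise unless the table can support model training."""
        if len(self) < 2:
            raise ValidationError("need at least 2 records to train")
        if self.data["outcome"].nunique() < 2:
            raise ValidationError("need at least 2 distinct outcome labels to train")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass(frozen=True)
class FeatureMatrix:
    """Numeric design matrix for a pattern of features."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.labels), len(self.feature_names)):
            raise ValueError("matrix shape inconsistent with names/labels")


def encode(table: CohortTable, pattern: Sequence[str]) -> FeatureMatrix:
    """Project a cohort onto a feature pattern as a numeric matrix.

    Categorical features pass through as their integer codes and continuous
    features as raw values (tree learners are scale-invariant).  Columns
    follow schema order restricted to ``pattern``; labels are the integer
    outcome codes.
    """
    names = list(pattern)
    if not names:
        raise ValueError("pattern must be non-empty")
    unknown = [n for n in names if n not in table.schema]
    if unknown:
        raise KeyError(f"not in schema: {unknown}")
    ordered = tuple(n for n in table.schema.feature_names if n in set(names))
    values = table.data.loc[:, list(ordered)].to_numpy(dtype=np.float64)
    return FeatureMatrix(values=values, feature_names=ordered, labels=table.outcome_codes)
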
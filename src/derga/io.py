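"""Reading and writing cohort tables (CSV / XLSX).

Cohort files carry 19 columns: the 18 schema features plus ``outcome``.
Column order is arbitrary; header matching is case-insensitive after
whitespace normalisation.  CSV is written with "." decimals and up to six
significant digits for continuous values so that a read/write round trip
reproduces the table exactly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .schema import CohortTable, FeatureSchema, SchemaError, default_schema

__all__ = ["read_cohort", "write_cohort"]


def _normalise_header(name: str) -> str:
    return " ".join(str(name).split()).strip().lower()


def read_cohort(path: str | Path, schema: FeatureSchema | None = None) -> CohortTable:
    """Load and validate a cohort table from a CSV or XLSX file.

    Raises
    ------
    SchemaError
        If a schema column is missing from the file.
    ValidationError
        If a row has a missing value, an out-of-level categorical code or an
        out-of-range continuous value (the message names the row index).
    """
    schema = schema or default_schema()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df = pd.read_excel(path, sheet_name=0, engine="openpyxl")
    else:
        df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: empty file")
    lut = {_normalise_header(c): c for c in df.columns}
    rename = {}
    for want in (*schema.feature_names, "outcome"):
        key = _normalise_header(want)
        if key not in lut:
            raise SchemaError(f"missing column: {want}")
        rename[lut[key]] = want
    df = df.rename(columns=rename)
    return CohortTable(df, schema=schema, provenance=f"real:{path}")


def _format_value(fdef_kind: str, v) -> str:
    if fdef_kind == "categorical":
        return str(int(v))
    return format(float(v), ".6g")


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort to CSV such that ``read_cohort`` reproduces it exactly.

    Continuous values are formatted to at most six significant digits; the
    synthetic generator rounds to the same precision, so the round trip is
    an identity for generated as well as loaded tables.
    """
    path = Path(path)
    out = table.data.copy()
    for fdef in table.schema.features:
        out[fdef.name] = [
            _format_value(fdef.kind, v) for v in out[fdef.name].to_numpy()
        ]
    out.to_csv(path, index=False)
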
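"""CSV table schemas and validated I/O for the pipeline.

All data flows through four flat CSV formats with a header row:

- ``binding_curve``: steady-state SPR titrations (TCR concentration in uM
  vs double-referenced response in RU) per ligand and replicate.
- ``antibody_trace``: W6/32 antibody binding time courses (s, RU).
- ``dose_response``: ligand dose vs % activation per experiment.
- ``potency_table``: (affinity, potency) pairs grouped by study /
  experiment / ligand, with either a ``kd_uM`` or a ``koff_per_s``
  affinity column and an optional ``flag`` column carrying exclusion
  reasons ("", "unreachable", "extrapolated", "below_threshold").

Units are fixed by convention (uM for concentrations and KD, s^-1 for
rates, RU for SPR response, % for activation) and recorded in run
metadata, keeping the dimensionless discrimination power alpha
unit-invariant.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

#: schema name -> (required columns, numeric columns, optional columns)
SCHEMAS: dict[str, tuple[list[str], list[str], list[str]]] = {
    "binding_curve": (
        ["ligand_id", "tcr_conc_uM", "response_RU"],
        ["tcr_conc_uM", "response_RU"],
        ["replicate_id"],
    ),
    "antibody_trace": (
        ["ligand_id", "time_s", "response_RU"],
        ["time_s", "response_RU"],
        [],
    ),
    "dose_response": (
        ["experiment_id", "ligand_id", "dose", "response_percent"],
        ["dose", "response_percent"],
        [],
    ),
    "potency_table": (
        ["study_id", "experiment_id", "ligand_id", "potency", "readout"],
        ["potency"],
        ["kd_uM", "koff_per_s", "flag"],
    ),
}


class TableError(ValueError):
    """A table failed schema validation."""


def _parse_float(value) -> float:
    try:
        return float(np.float64(value))
    except (TypeError, ValueError):
        return np.nan


def _validate(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    required, numeric, optional = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"{schema}: missing required columns {missing}")
    if schema == "potency_table" and not (
            "kd_uM" in df.columns or "koff_per_s" in df.columns):
        raise TableError("potency_table: needs a kd_uM or koff_per_s column")
    if df.empty:
        raise TableError(f"{schema}: empty table")
    numeric = list(numeric)
    if schema == "potency_table":
        numeric += [c for c in ("kd_uM", "koff_per_s") if c in df.columns]
    for col in numeric:
        # numpy's parser is correctly rounded, so decimal-text round-trips
        # are exact (pandas' fast parser is not)
        coerced = df[col].map(_parse_float)
        bad = coerced.isna()
        # rows flagged as excluded may legitimately carry a missing potency
        if schema == "potency_table" and col == "potency" and "flag" in df.columns:
            flagged = df["flag"].fillna("").astype(str) != ""
            bad = bad & ~flagged
        if bad.any():
            rows = [int(i) + 2 for i in df.index[bad]]  # 1-based incl. header
            raise TableError(
                f"{schema}: non-numeric or missing value in column "
                f"'{col}' at file row(s) {rows}")
        df = df.assign(**{col: coerced})
    if schema == "potency_table" and "flag" in df.columns:
        df = df.assign(flag=df["flag"].fillna("").astype(str))
    return df


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a pipeline CSV; raises :class:`TableError` on
    unknown schema, missing columns, empty tables or non-numeric cells
    (naming the offending file row)."""
    if schema not in SCHEMAS:
        raise TableError(f"unknown schema '{schema}'; know {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    return _validate(df, schema)


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> Path:
    """Write a pipeline CSV (validating against the schema first).

    Floats are written with repr-precision so that write/read round-trips
    are exact on the decimal text.
    """
    if schema not in SCHEMAS:
        raise TableError(f"unknown schema '{schema}'; know {sorted(SCHEMAS)}")
    required, _, optional = SCHEMAS[schema]
    cols = [c for c in required + optional if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df[cols + extra].copy()
    out.to_csv(path, index=False, float_format="%.17g")
    return path
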
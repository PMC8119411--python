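"""CSV readers/writers with fixed schemas and row-level validation.

All interchange is plain CSV with a decimal point, ISO-8601 dates and
``YYYY-MM`` month keys. Readers reject malformed rows with their line
numbers rather than silently dropping them.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError, ValidationError
from .fai import FAISeries
from .types import (
    CLASS_ORDER,
    INDIVIDUAL_COLUMNS,
    PHENOLOGY_COLUMNS,
    SAMPLE_COLUMNS,
    TRUTH_COLUMNS,
)

__all__ = [
    "read_fai",
    "read_individuals",
    "read_phenology",
    "read_samples",
    "write_fai",
    "write_individuals",
    "write_phenology",
    "write_samples",
    "write_truth",
]


def _require_columns(frame: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _lines(frame_index) -> str:
    # +2: header line plus 1-based indexing
    return ", ".join(str(i + 2) for i in list(frame_index)[:20])


def read_samples(path) -> pd.DataFrame:
    """Read and validate a urine-sample table.

    Columns: ``sample_id, individual_id, date, specific_gravity,
    creatinine_mg_ml``. Dates must parse as ISO-8601; SG must be > 1.0
    and creatinine >= 0.
    """
    frame = pd.read_csv(path, dtype={"sample_id": str, "individual_id": str})
    _require_columns(frame, SAMPLE_COLUMNS, path)
    dates = pd.to_datetime(frame["date"], format="ISO8601", errors="coerce")
    bad = frame.index[dates.isna()]
    if len(bad):
        raise SchemaError(f"{path}: unparseable ISO-8601 date on line(s) {_lines(bad)}")
    frame["date"] = dates.dt.date
    for col in ("specific_gravity", "creatinine_mg_ml"):
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[values.isna()]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric {col} on line(s) {_lines(bad)}")
        frame[col] = values
    bad = frame.index[frame["specific_gravity"] <= 1.0]
    if len(bad):
        ids = frame.loc[bad, "sample_id"].tolist()[:10]
        raise ValidationError(
            f"{path}: specific_gravity <= 1.0 on line(s) {_lines(bad)} "
            f"(sample ids: {', '.join(ids)})"
        )
    bad = frame.index[frame["creatinine_mg_ml"] < 0]
    if len(bad):
        raise ValidationError(f"{path}: negative creatinine on line(s) {_lines(bad)}")
    if frame["sample_id"].duplicated().any():
        dupes = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()[:10]
        raise ValidationError(f"{path}: duplicate sample ids: {', '.join(dupes)}")
    return frame[list(SAMPLE_COLUMNS)]


def write_samples(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, columns=list(SAMPLE_COLUMNS))


def read_individuals(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str)
    _require_columns(frame, INDIVIDUAL_COLUMNS, path)
    bad = frame.index[~frame["age_sex_class"].isin(CLASS_ORDER)]
    if len(bad):
        raise ValidationError(
            f"{path}: unknown age_sex_class on line(s) {_lines(bad)}; "
            f"expected one of {', '.join(CLASS_ORDER)}"
        )
    if frame["individual_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate individual ids")
    return frame[list(INDIVIDUAL_COLUMNS)]


def write_individuals(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, columns=list(INDIVIDUAL_COLUMNS))


def read_phenology(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"month": str, "stem_id": str})
    _require_columns(frame, PHENOLOGY_COLUMNS, path)
    bad = frame.index[~frame["month"].str.fullmatch(r"\d{4}-\d{2}")]
    if len(bad):
        raise SchemaError(f"{path}: month not YYYY-MM on line(s) {_lines(bad)}")
    dbh = pd.to_numeric(frame["dbh_cm"], errors="coerce")
    bad = frame.index[dbh.isna() | (dbh <= 0)]
    if len(bad):
        raise ValidationError(f"{path}: dbh_cm must be numeric and > 0; line(s) {_lines(bad)}")
    frame["dbh_cm"] = dbh
    fruiting = pd.to_numeric(frame["fruiting"], errors="coerce")
    bad = frame.index[~fruiting.isin([0, 1])]
    if len(bad):
        raise ValidationError(f"{path}: fruiting must be 0/1; line(s) {_lines(bad)}")
    frame["fruiting"] = fruiting.astype(int)
    return frame[list(PHENOLOGY_COLUMNS)]


def write_phenology(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, columns=list(PHENOLOGY_COLUMNS))


def write_truth(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, columns=list(TRUTH_COLUMNS))


def write_fai(series: FAISeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_fai(path, tie_rule: str = "strict_greater") -> FAISeries:
    frame = pd.read_csv(path, dtype={"month": str})
    _require_columns(frame, ("month", "fai_percent"), path)
    return FAISeries.from_frame(frame, tie_rule=tie_rule)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
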
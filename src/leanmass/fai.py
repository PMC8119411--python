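"""Monthly fruit availability index (FAI) from phenology censuses.

The FAI of a month is the percentage of censused stems with dbh strictly
greater than 10 cm that are fruiting; stems at or below 10 cm are excluded
from both numerator and denominator. Monthly values are split into
categorical high/low periods at the median of the series.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import MissingMonthError, UndefinedIndexError, ValidationError

__all__ = [
    "DBH_THRESHOLD_CM",
    "FAISeries",
    "attach_fai",
    "binarize_fai",
    "compute_fai",
    "fai_series_from_phenology",
]

DBH_THRESHOLD_CM = 10.0


@dataclasses.dataclass
class FAISeries:
    """Ordered month -> FAI-percent map with the median split.

    ``labels[m]`` is ``"high"`` when ``entries[m]`` exceeds ``median_fai``
    under the configured tie rule, else ``"low"``.
    """

    entries: dict[str, float]
    median_fai: float | None = None
    labels: dict[str, str] = dataclasses.field(default_factory=dict)
    tie_rule: str = "strict_greater"

    def __post_init__(self) -> None:
        for month, value in self.entries.items():
            if not 0.0 <= value <= 100.0:
                raise ValidationError(f"FAI for {month} outside [0, 100]: {value}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": list(self.entries),
                "fai_percent": list(self.entries.values()),
                "fai_label": [self.labels.get(m, "") for m in self.entries],
                "median_fai": self.median_fai,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, tie_rule: str = "strict_greater") -> "FAISeries":
        entries = dict(zip(frame["month"].astype(str), frame["fai_percent"].astype(float)))
        series = cls(entries=entries, tie_rule=tie_rule)
        return binarize_fai(series)


def compute_fai(census: pd.DataFrame, dbh_threshold: float = DBH_THRESHOLD_CM) -> float:
    """FAI percent for a single month's census records.

    ``census`` needs columns ``dbh_cm`` and ``fruiting``. Raises
    :class:`UndefinedIndexError` when no stem exceeds the dbh threshold —
    the index is undefined there, not zero.
    """
    if (census["dbh_cm"] <= 0).any():
        raise ValidationError("dbh_cm must be > 0 for every stem")
    eligible = census.loc[census["dbh_cm"] > dbh_threshold]
    if eligible.empty:
        raise UndefinedIndexError(
            f"FAI undefined: no stems with dbh > {dbh_threshold} cm in census"
        )
    return 100.0 * float(eligible["fruiting"].astype(bool).sum()) / float(len(eligible))


def binarize_fai(series: FAISeries) -> FAISeries:
    """Fill ``median_fai`` and the high/low labels of a series in place.

    ``tie_rule == "strict_greater"`` labels a month high iff its value is
    strictly above the median (months at the median are low);
    ``"greater_equal"`` labels months at the median high.
    """
    if not series.entries:
        raise ValidationError("cannot binarize an empty FAI series")
    if series.tie_rule not in ("strict_greater", "greater_equal"):
        raise ValidationError(f"unknown tie rule {series.tie_rule!r}")
    values = np.array(list(series.entries.values()), dtype=float)
    median = float(np.median(values))
    if series.tie_rule == "strict_greater":
        high = values > median
    else:
        high = values >= median
    series.median_fai = median
    series.labels = {
        month: ("high" if h else "low") for month, h in zip(series.entries, high)
    }
    return series


def fai_series_from_phenology(
    phenology: pd.DataFrame,
    dbh_threshold: float = DBH_THRESHOLD_CM,
    tie_rule: str = "strict_greater",
) -> FAISeries:
    """Compute the monthly FAI series from a tidy phenology table.

    ``phenology`` has one row per stem per month with columns
    ``month, stem_id, dbh_cm, fruiting``; stem ids must be unique within a
    month.
    """
    dup = phenology.duplicated(subset=["month", "stem_id"])
    if dup.any():
        months = sorted(phenology.loc[dup, "month"].unique())
        raise ValidationError(f"duplicate stem_id within months: {', '.join(map(str, months))}")
    entries: dict[str, float] = {}
    for month, census in phenology.groupby("month", sort=True):
        entries[str(month)] = compute_fai(census, dbh_threshold)
    return binarize_fai(FAISeries(entries=entries, tie_rule=tie_rule))


def attach_fai(samples: pd.DataFrame, series: FAISeries) -> pd.DataFrame:
    """Annotate each sample with its collection month's FAI and label.

    Adds columns ``month``, ``fai_percent`` and ``fai_label``; all other
    columns and the row count are preserved. Raises
    :class:`MissingMonthError` listing any months absent from the series.
    """
    if not series.labels or series.median_fai is None:
        series = binarize_fai(series)
    months = pd.to_datetime(samples["date"]).dt.strftime("%Y-%m")
    missing = set(months) - set(series.entries)
    if missing:
        raise MissingMonthError(missing)
    annotated = samples.copy()
    annotated["month"] = months.to_numpy()
    annotated["fai_percent"] = months.map(series.entries).to_numpy()
    annotated["fai_label"] = months.map(series.labels).to_numpy()
    return annotated
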
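"""Dilute-sample filtering, through-origin calibration and ELBM residuals.

Creatinine and specific gravity (SG) both track urine concentration, but
only creatinine scales with muscle mass. After dropping overly dilute
samples (SG below a threshold, default 1.003) a single global
least-squares fit of creatinine on ``(SG - 1)`` and ``(SG - 1)**2`` with
no intercept is computed; its residuals are the estimated lean body mass
(ELBM), on the creatinine mg/ml scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    InsufficientDataError,
    SingularDesignError,
    ValidationError,
)
from .types import CLASS_ORDER

__all__ = [
    "CalibrationFit",
    "compute_elbm",
    "filter_dilute",
    "fit_calibration",
    "sg_features",
    "summarize_by_class",
    "validate_samples",
]

SG_THRESHOLD_DEFAULT = 1.003


def validate_samples(samples: pd.DataFrame) -> None:
    """Enforce the physical invariants SG > 1.0 and creatinine >= 0."""
    bad_sg = samples.loc[samples["specific_gravity"] <= 1.0, "sample_id"]
    if len(bad_sg):
        raise ValidationError(
            "specific_gravity must be > 1.000 (water = 1.0); offending samples: "
            + ", ".join(map(str, bad_sg.tolist()[:20]))
        )
    bad_cr = samples.loc[samples["creatinine_mg_ml"] < 0, "sample_id"]
    if len(bad_cr):
        raise ValidationError(
            "creatinine_mg_ml must be >= 0; offending samples: "
            + ", ".join(map(str, bad_cr.tolist()[:20]))
        )


def filter_dilute(
    samples: pd.DataFrame, threshold: float = SG_THRESHOLD_DEFAULT
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split samples into (kept, excluded) by the dilute-SG rule.

    Excluded are exactly the rows with ``specific_gravity < threshold``
    (strict: a sample at exactly the threshold is kept). Row order is
    preserved in both outputs.
    """
    validate_samples(samples)
    dilute = samples["specific_gravity"] < threshold
    return samples.loc[~dilute].copy(), samples.loc[dilute].copy()


def sg_features(specific_gravity) -> tuple[np.ndarray, np.ndarray]:
    """Return the regression features ``(SG - 1, (SG - 1)**2)``.

    Accepts a scalar or array; validates SG > 1.0.
    """
    sg = np.asarray(specific_gravity, dtype=float)
    if np.any(sg <= 1.0):
        raise ValidationError("specific_gravity must be > 1.0")
    x = sg - 1.0
    return x, x * x


@dataclasses.dataclass
class CalibrationFit:
    """Through-origin creatinine ~ SG fit with residuals and audit trail.

    ``mode == "two_coefficients"`` fits ``b1*(SG-1) + b2*(SG-1)^2`` with
    two free coefficients; ``mode == "single_regressor"`` fits one
    coefficient on the combined regressor ``(SG-1) + (SG-1)^2`` (then
    ``b2 == b1`` by construction).
    """

    b1: float
    b2: float
    mode: str
    residuals: pd.Series
    fitted: pd.Series
    r2_uncentered: float
    r2_adj: float
    n_used: int
    n_excluded: int
    excluded_ids: tuple[str, ...]

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.b1, self.b2])

    def predict(self, specific_gravity) -> np.ndarray:
        lin, quad = sg_features(specific_gravity)
        return self.b1 * lin + self.b2 * quad

    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": [
                    "b1",
                    "b2",
                    "mode",
                    "r2_uncentered",
                    "r2_adj",
                    "n_used",
                    "n_excluded",
                ],
                "value": [
                    self.b1,
                    self.b2,
                    self.mode,
                    self.r2_uncentered,
                    self.r2_adj,
                    self.n_used,
                    self.n_excluded,
                ],
            }
        )


def fit_calibration(
    kept: pd.DataFrame,
    mode: str = "two_coefficients",
    excluded: pd.DataFrame | None = None,
) -> CalibrationFit:
    """Least-squares through-origin fit of creatinine on SG features.

    Solved by orthogonal decomposition (SVD-based ``lstsq``), not by
    explicit normal-equations inversion; residuals are orthogonal to both
    predictor columns to numerical tolerance. The uncentered R-squared is
    ``1 - SSR / sum(y^2)`` (the natural definition for a no-intercept
    model) and the adjusted version uses residual df ``n - p``.
    """
    if mode not in ("two_coefficients", "single_regressor"):
        raise ValidationError(f"unknown calibration mode {mode!r}")
    n = len(kept)
    if n < 3:
        raise InsufficientDataError(f"calibration needs >= 3 samples, got {n}")
    validate_samples(kept)
    lin, quad = sg_features(kept["specific_gravity"].to_numpy())
    if np.unique(lin).size < 2:
        raise SingularDesignError("all specific gravities identical; design is singular")
    y = kept["creatinine_mg_ml"].to_numpy(dtype=float)

    if mode == "two_coefficients":
        X = np.column_stack([lin, quad])
    else:
        X = (lin + quad)[:, None]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    p = X.shape[1]
    ss_total = float(y @ y)
    ssr = float(resid @ resid)
    r2 = 1.0 - ssr / ss_total if ss_total > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * n / (n - p) if n > p else np.nan

    b1, b2 = (float(coef[0]), float(coef[1])) if mode == "two_coefficients" else (
        float(coef[0]),
        float(coef[0]),
    )
    ids = kept["sample_id"].astype(str)
    excluded_ids = (
        tuple(excluded["sample_id"].astype(str)) if excluded is not None else ()
    )
    return CalibrationFit(
        b1=b1,
        b2=b2,
        mode=mode,
        residuals=pd.Series(resid, index=ids, name="elbm"),
        fitted=pd.Series(fitted, index=ids, name="fitted"),
        r2_uncentered=r2,
        r2_adj=float(r2_adj),
        n_used=n,
        n_excluded=len(excluded_ids),
        excluded_ids=excluded_ids,
    )


def compute_elbm(kept: pd.DataFrame, fit: CalibrationFit) -> pd.DataFrame:
    """One ELBM row per kept sample: the calibration residual.

    Raises :class:`ConsistencyError` if any sample id is missing from the
    fit (the fit must have been produced from exactly these samples).
    """
    ids = kept["sample_id"].astype(str)
    missing = set(ids) - set(fit.residuals.index)
    if missing:
        raise ConsistencyError(
            "samples absent from calibration fit: " + ", ".join(sorted(missing)[:10])
        )
    out = kept[["sample_id", "individual_id", "date"]].copy()
    out["month"] = pd.to_datetime(kept["date"]).dt.strftime("%Y-%m").to_numpy()
    out["elbm"] = fit.residuals.loc[ids].to_numpy()
    return out.reset_index(drop=True)


def summarize_by_class(elbm_table: pd.DataFrame, individuals: pd.DataFrame) -> pd.DataFrame:
    """Per-class summary of ELBM: n, mean, SD (ddof=1), median, IQR.

    IQR is Q3 - Q1 with linear-interpolation quantiles. Classes are
    reported in canonical order; only classes present appear.
    """
    class_of = dict(zip(individuals["individual_id"], individuals["age_sex_class"]))
    unresolved = sorted(set(elbm_table["individual_id"]) - set(class_of))
    if unresolved:
        raise ConsistencyError(
            "individuals missing an age-sex class: " + ", ".join(unresolved[:10])
        )
    work = elbm_table.assign(
        age_sex_class=elbm_table["individual_id"].map(class_of)
    )
    rows = []
    for cls in CLASS_ORDER:
        values = work.loc[work["age_sex_class"] == cls, "elbm"].to_numpy(dtype=float)
        if values.size == 0:
            continue
        q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
        rows.append(
            {
                "age_sex_class": cls,
                "n": int(values.size),
                "mean": float(values.mean()),
                "sd": float(values.std(ddof=1)) if values.size > 1 else np.nan,
                "median": float(med),
                "iqr": float(q3 - q1),
            }
        )
    return pd.DataFrame(rows)
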
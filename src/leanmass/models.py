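"""Mixed-model analysis of ELBM against fruit availability and class.

Two models are provided:

* :func:`fit_gamm` — additive mixed model: treatment-coded age-sex class
  fixed effects, a penalized cubic regression spline of continuous FAI
  (smoothing parameter chosen by REML), and a Gaussian random intercept
  per individual.
* :func:`fit_glmm_binary` — linear mixed model with FAI binned high/low
  (identity link, Gaussian response) for visualisation-style predictions.

Pairwise class comparisons follow the releveling strategy: the model is
refitted once per baseline class and the non-baseline coefficient rows
are collected. Inference is approximate: Wald t statistics with
``n - edf_total`` residual degrees of freedom for fixed effects, and a
rank-adjusted Wald F test on the fitted smooth for the FAI term.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, ModelSpecError, ValidationError
from .fai import FAISeries, attach_fai
from .mixed import MixedFit, fit_reml
from .smoothing import CubicSmooth
from .types import CLASS_ORDER

__all__ = [
    "ContrastTable",
    "ModelResult",
    "fit_gamm",
    "fit_glmm_binary",
    "pairwise_contrasts",
    "predict_elbm",
]

FAI_LEVELS = ("high", "low")  # "high" is the reference level


@dataclasses.dataclass
class SmoothSummary:
    edf: float
    f_stat: float
    p_value: float


@dataclasses.dataclass
class ModelResult:
    """Coefficient table plus variance components of one mixed-model fit."""

    coefficient_rows: pd.DataFrame  # term, estimate, se, t_stat, p_value
    smooth_summary: SmoothSummary | None
    random_intercept_sd: float
    residual_sd: float
    r2_adj: float
    baseline_class: str
    n_obs: int
    n_groups: int
    # fitted state for prediction / diagnostics
    _fit: MixedFit | None = dataclasses.field(default=None, repr=False)
    _smooth: CubicSmooth | None = dataclasses.field(default=None, repr=False)
    _classes: tuple[str, ...] = ()
    _terms: tuple[str, ...] = ()
    _fai_reference: str | None = None
    _interaction: bool = False

    @property
    def loglik(self) -> float:
        return self._fit.reml_loglik if self._fit is not None else np.nan

    @property
    def fitted(self) -> np.ndarray:
        return self._fit.fitted if self._fit is not None else np.array([])

    def coefficient(self, term: str) -> pd.Series:
        rows = self.coefficient_rows.set_index("term")
        if term not in rows.index:
            raise KeyError(term)
        return rows.loc[term]

    def predict_smooth(self, fai_grid: np.ndarray) -> pd.DataFrame:
        """Centred smooth-term estimate f(FAI) with standard errors."""
        if self._smooth is None or self._fit is None:
            raise ModelSpecError("model has no active smooth term")
        fit = self._fit
        null_col, wiggle = self._smooth.design(np.asarray(fai_grid, dtype=float))
        s = fit.block_slices["smooth"]
        scale = np.sqrt(fit.theta["smooth"])
        lin_idx = self._terms.index("s(fai):linear")
        F = np.column_stack([null_col, scale * wiggle])
        idx = np.r_[lin_idx, fit.p + np.arange(s.start, s.stop)]
        d = np.r_[fit.beta[lin_idx], fit.u[s]]
        V = fit.cov_coef[np.ix_(idx, idx)]
        est = F @ d
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", F, V, F), 0.0))
        return pd.DataFrame({"fai_percent": np.asarray(fai_grid), "estimate": est, "se": se})


@dataclasses.dataclass
class ContrastTable:
    """Pairwise class contrasts from releveled refits.

    ``rows`` holds each unordered pair once (baseline earlier in
    canonical class order); ``rows_all`` holds both directions.
    """

    rows: pd.DataFrame
    rows_all: pd.DataFrame


def _class_map(elbm_table: pd.DataFrame, individuals: pd.DataFrame) -> pd.Series:
    lookup = dict(zip(individuals["individual_id"], individuals["age_sex_class"]))
    missing = sorted(set(elbm_table["individual_id"]) - set(lookup))
    if missing:
        raise ConsistencyError("individuals without a class: " + ", ".join(missing[:10]))
    return elbm_table["individual_id"].map(lookup)


def _class_design(classes: pd.Series, baseline: str) -> tuple[np.ndarray, list[str]]:
    present = [c for c in CLASS_ORDER if c in set(classes)]
    if baseline not in present:
        raise ModelSpecError(f"baseline class {baseline!r} not present in data")
    if len(present) < 2:
        raise ModelSpecError("at least two age-sex classes are required")
    others = [c for c in present if c != baseline]
    cols = [np.ones(len(classes))]
    names = ["intercept"]
    for c in others:
        cols.append((classes == c).to_numpy(dtype=float))
        names.append(f"class[{c}]")
    return np.column_stack(cols), names


def _indicator(ids: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(ids.unique())
    Z = (ids.to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)
    return Z, levels


def _wald_rows(fit: MixedFit, names: list[str]) -> pd.DataFrame:
    se = np.sqrt(np.diag(fit.cov_beta))
    df = max(fit.n - fit.edf_total, 1.0)
    t = np.divide(fit.beta, se, out=np.zeros_like(fit.beta), where=se > 0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {"term": names, "estimate": fit.beta, "se": se, "t_stat": t, "p_value": p}
    )


def _smooth_test(fit: MixedFit, lin_idx: int, null_col, wiggle) -> SmoothSummary:
    """Rank-adjusted Wald test of the whole smooth (linear + wiggle).

    The statistic is built on the fitted function values using the
    Bayesian coefficient covariance, with the pseudo-inverse truncated at
    a rank driven by the smooth's effective degrees of freedom.
    """
    s = fit.block_slices["smooth"]
    scale = np.sqrt(fit.theta["smooth"])
    F = np.column_stack([null_col, scale * wiggle])
    idx = np.r_[lin_idx, fit.p + np.arange(s.start, s.stop)]
    d = np.r_[fit.beta[lin_idx], fit.u[s]]
    V = fit.cov_coef[np.ix_(idx, idx)]

    edf = fit.edf[lin_idx] + fit.edf_block("smooth")
    # Reduce to the (k-1)-dimensional column space of F.
    _, R = np.linalg.qr(F)
    g = R @ d
    Vg = R @ V @ R.T
    fl = int(np.floor(edf))
    rank = fl + 1 if edf - fl > 0.05 else fl
    rank = int(max(1, min(rank, len(g))))
    eigval, eigvec = np.linalg.eigh(Vg)
    order = np.argsort(eigval)[::-1]
    keep = order[:rank]
    pos = eigval[keep] > eigval[order[0]] * 1e-12
    keep = keep[pos]
    proj = eigvec[:, keep].T @ g
    T = float(np.sum(proj**2 / eigval[keep]))
    rank = len(keep)
    df2 = max(fit.n - fit.edf_total, 1.0)
    f_stat = T / rank
    p = float(stats.f.sf(f_stat, rank, df2))
    return SmoothSummary(edf=float(edf), f_stat=float(f_stat), p_value=p)


def _degenerate_result(
    elbm_table, classes, baseline, present, smooth_active
) -> ModelResult:
    names = ["intercept"] + [f"class[{c}]" for c in present if c != baseline]
    rows = pd.DataFrame(
        {
            "term": names,
            "estimate": 0.0,
            "se": np.nan,
            "t_stat": np.nan,
            "p_value": np.nan,
        }
    )
    smooth = SmoothSummary(edf=1.0, f_stat=0.0, p_value=1.0) if smooth_active else None
    return ModelResult(
        coefficient_rows=rows,
        smooth_summary=smooth,
        random_intercept_sd=0.0,
        residual_sd=0.0,
        r2_adj=np.nan,
        baseline_class=baseline,
        n_obs=len(elbm_table),
        n_groups=elbm_table["individual_id"].nunique(),
    )


def fit_gamm(
    elbm_table: pd.DataFrame,
    individuals: pd.DataFrame,
    fai_series: FAISeries | None = None,
    baseline_class: str = "adult_female",
    basis_dim: int = 10,
    smooth: bool = True,
) -> ModelResult:
    """Additive mixed model: ELBM ~ class + s(FAI) + (1 | individual).

    ``elbm_table`` needs ``fai_percent`` attached (or pass ``fai_series``
    to attach it here). ``smooth=False`` drops the FAI term entirely,
    leaving a plain random-intercept model on class.
    """
    table = elbm_table
    if smooth and "fai_percent" not in table.columns:
        if fai_series is None:
            raise ValidationError("elbm_table lacks fai_percent and no fai_series given")
        table = attach_fai(table, fai_series)
    classes = _class_map(table, individuals)
    present = tuple(c for c in CLASS_ORDER if c in set(classes))
    if len(present) < 2:
        raise ModelSpecError("at least two age-sex classes are required")

    y = table["elbm"].to_numpy(dtype=float)
    if np.ptp(y) < 1e-12:
        return _degenerate_result(table, classes, baseline_class, present, smooth)

    X, names = _class_design(classes, baseline_class)
    blocks: dict[str, np.ndarray] = {}
    Z_ind, groups = _indicator(table["individual_id"].astype(str))
    blocks["individual"] = Z_ind

    cubic = None
    null_col = wiggle = None
    if smooth:
        cubic = CubicSmooth.from_data(table["fai_percent"].to_numpy(dtype=float), basis_dim)
        null_col, wiggle = cubic.design(table["fai_percent"].to_numpy(dtype=float))
        X = np.column_stack([X, null_col])
        names = names + ["s(fai):linear"]
        blocks["smooth"] = wiggle

    fit = fit_reml(y, X, blocks)

    class_rows = _wald_rows(fit, names)
    smooth_summary = None
    if smooth:
        lin_idx = names.index("s(fai):linear")
        smooth_summary = _smooth_test(fit, lin_idx, null_col, wiggle)
        class_rows = class_rows[class_rows["term"] != "s(fai):linear"].reset_index(drop=True)

    rss = float(fit.residuals @ fit.residuals)
    tss = float(((y - y.mean()) ** 2).sum())
    n = fit.n
    r2_adj = 1.0 - (rss / max(n - fit.edf_total, 1.0)) / (tss / (n - 1)) if tss > 0 else np.nan

    return ModelResult(
        coefficient_rows=class_rows,
        smooth_summary=smooth_summary,
        random_intercept_sd=fit.block_sd("individual"),
        residual_sd=fit.residual_sd,
        r2_adj=float(r2_adj),
        baseline_class=baseline_class,
        n_obs=n,
        n_groups=len(groups),
        _fit=fit,
        _smooth=cubic,
        _classes=present,
        _terms=tuple(names),
    )


def pairwise_contrasts(
    elbm_table: pd.DataFrame,
    individuals: pd.DataFrame,
    fai_series: FAISeries | None = None,
    basis_dim: int = 10,
    smooth: bool = True,
    dedupe: bool = True,
) -> ContrastTable:
    """All pairwise class contrasts via releveled refits.

    Each present class is taken as baseline in turn; the non-baseline
    coefficient rows are collected. With ``dedupe=True`` (default) each
    unordered pair is reported once, from the baseline that comes first
    in canonical class order; ``rows_all`` always carries both directions.
    """
    table = elbm_table
    if "fai_percent" not in table.columns and fai_series is not None:
        table = attach_fai(table, fai_series)
    classes = _class_map(table, individuals)
    present = [c for c in CLASS_ORDER if c in set(classes)]
    records = []
    for baseline in present:
        result = fit_gamm(
            table, individuals, baseline_class=baseline, basis_dim=basis_dim, smooth=smooth
        )
        rows = result.coefficient_rows
        for _, row in rows[rows["term"] != "intercept"].iterrows():
            other = row["term"][len("class[") : -1]
            records.append(
                {
                    "baseline_class": baseline,
                    "other_class": other,
                    "estimate": row["estimate"],
                    "se": row["se"],
                    "t_stat": row["t_stat"],
                    "p_value": row["p_value"],
                }
            )
    rows_all = pd.DataFrame(records)
    order = {c: i for i, c in enumerate(CLASS_ORDER)}
    keep = rows_all[
        rows_all.apply(lambda r: order[r["baseline_class"]] < order[r["other_class"]], axis=1)
    ].reset_index(drop=True)
    return ContrastTable(rows=keep if dedupe else rows_all, rows_all=rows_all)


def fit_glmm_binary(
    elbm_table: pd.DataFrame,
    individuals: pd.DataFrame,
    include_interaction: bool = False,
    baseline_class: str = "adult_female",
) -> ModelResult:
    """Linear mixed model: ELBM ~ FAI(high/low) + class (+ interaction).

    Gaussian response with identity link and a random intercept per
    individual. "high" FAI is the reference level, so the ``fai[low]``
    coefficient is the low-minus-high ELBM difference.
    """
    if "fai_label" not in elbm_table.columns:
        raise ValidationError("elbm_table lacks fai_label; attach the FAI series first")
    labels = set(elbm_table["fai_label"])
    if not {"high", "low"} <= labels:
        raise ModelSpecError(f"need both FAI levels present, got {sorted(labels)}")
    classes = _class_map(elbm_table, individuals)
    present = tuple(c for c in CLASS_ORDER if c in set(classes))

    y = elbm_table["elbm"].to_numpy(dtype=float)
    X, names = _class_design(classes, baseline_class)
    low = (elbm_table["fai_label"] == "low").to_numpy(dtype=float)
    X = np.column_stack([X, low])
    names.append("fai[low]")
    if include_interaction:
        for c in present:
            if c == baseline_class:
                continue
            X = np.column_stack([X, low * (classes == c).to_numpy(dtype=float)])
            names.append(f"fai[low]:class[{c}]")

    Z_ind, groups = _indicator(elbm_table["individual_id"].astype(str))
    if np.ptp(y) < 1e-12:
        return _degenerate_result(elbm_table, classes, baseline_class, present, False)
    fit = fit_reml(y, X, {"individual": Z_ind})

    rss = float(fit.residuals @ fit.residuals)
    tss = float(((y - y.mean()) ** 2).sum())
    r2_adj = (
        1.0 - (rss / max(fit.n - fit.edf_total, 1.0)) / (tss / (fit.n - 1)) if tss > 0 else np.nan
    )
    return ModelResult(
        coefficient_rows=_wald_rows(fit, names),
        smooth_summary=None,
        random_intercept_sd=fit.block_sd("individual"),
        residual_sd=fit.residual_sd,
        r2_adj=float(r2_adj),
        baseline_class=baseline_class,
        n_obs=fit.n,
        n_groups=len(groups),
        _fit=fit,
        _classes=present,
        _terms=tuple(names),
        _fai_reference="high",
        _interaction=include_interaction,
    )


def predict_elbm(model: ModelResult, grid: pd.DataFrame) -> pd.DataFrame:
    """Population-level predictions (random intercept at zero) with SEs.

    ``grid`` has columns ``age_sex_class`` and ``fai_label``; every level
    must have been present in the training data.
    """
    if model._fit is None:
        raise ModelSpecError("model carries no fitted state")
    if model._fai_reference is None:
        raise ModelSpecError("predict_elbm requires the binary-FAI model")
    unseen = sorted(set(grid["age_sex_class"]) - set(model._classes))
    if unseen:
        raise ModelSpecError("unseen class level(s): " + ", ".join(unseen))
    bad = sorted(set(grid["fai_label"]) - set(FAI_LEVELS))
    if bad:
        raise ModelSpecError("unknown FAI level(s): " + ", ".join(map(str, bad)))

    terms = list(model._terms)
    rows = np.zeros((len(grid), len(terms)))
    rows[:, terms.index("intercept")] = 1.0
    for i, (_, cell) in enumerate(grid.iterrows()):
        cls, lab = cell["age_sex_class"], cell["fai_label"]
        if f"class[{cls}]" in terms:
            rows[i, terms.index(f"class[{cls}]")] = 1.0
        if lab == "low":
            rows[i, terms.index("fai[low]")] = 1.0
            inter = f"fai[low]:class[{cls}]"
            if inter in terms:
                rows[i, terms.index(inter)] = 1.0

    fit = model._fit
    est = rows @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", rows, fit.cov_beta, rows), 0.0))
    out = grid.copy().reset_index(drop=True)
    out["estimate"] = est
    out["se"] = se
    return out
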
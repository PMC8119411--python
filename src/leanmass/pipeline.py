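"""End-to-end pipeline driver with a reproducibility manifest.

Stage order: phenology -> FAI -> attach -> dilute filter -> calibration
-> ELBM -> class summaries -> GAMM + relevel contrasts -> binary-FAI
mixed model -> predictions -> plots. Every run writes ``manifest.json``
echoing the configuration, seed, software version and the row counts at
each stage boundary, so any artifact can be regenerated byte-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import io
from ._version import __version__
from .config import PipelineConfig
from .elbm import compute_elbm, filter_dilute, fit_calibration, summarize_by_class
from .errors import PipelineStageError
from .fai import attach_fai, fai_series_from_phenology
from .models import fit_gamm, fit_glmm_binary, pairwise_contrasts, predict_elbm
from .types import CLASS_ORDER

__all__ = ["run_pipeline"]

logger = logging.getLogger("leanmass")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return the manifest (also written to disk).

    Any stage failure raises :class:`PipelineStageError` naming the stage;
    artifacts written by earlier stages are preserved.
    """
    out = io.ensure_dir(config.output_dir)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "counts": {},
        "statistics": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                _write_manifest(manifest, out)
                raise PipelineStageError(name, exc) from exc

        return wrap

    samples = stage("read_samples")(lambda: io.read_samples(config.samples_path))
    individuals = stage("read_individuals")(lambda: io.read_individuals(config.individuals_path))
    phenology = stage("read_phenology")(lambda: io.read_phenology(config.phenology_path))
    manifest["counts"]["n_input"] = len(samples)
    manifest["counts"]["n_individuals"] = len(individuals)
    manifest["counts"]["n_phenology_rows"] = len(phenology)

    series = stage("fai")(
        lambda: fai_series_from_phenology(phenology, tie_rule=config.fai_tie_rule)
    )
    io.write_fai(series, out / "fai.csv")
    manifest["statistics"]["median_fai"] = series.median_fai
    logger.info("FAI: %d months, median %.3f", len(series.entries), series.median_fai)

    kept, excluded = stage("filter_dilute")(
        lambda: filter_dilute(samples, threshold=config.sg_threshold)
    )
    manifest["counts"]["n_used"] = len(kept)
    manifest["counts"]["n_excluded"] = len(excluded)
    logger.info("dilute filter: kept %d, excluded %d", len(kept), len(excluded))

    fit = stage("calibration")(
        lambda: fit_calibration(kept, mode=config.calibration_mode, excluded=excluded)
    )
    fit.report_frame().to_csv(out / "calibration_report.csv", index=False)
    (out / "calibration.log").write_text(
        "through-origin calibration creatinine ~ (SG-1) + (SG-1)^2\n"
        f"mode          : {fit.mode}\n"
        f"b1            : {fit.b1:.6f}\n"
        f"b2            : {fit.b2:.6f}\n"
        f"r2_uncentered : {fit.r2_uncentered:.6f}\n"
        f"r2_adj        : {fit.r2_adj:.6f}\n"
        f"n_used        : {fit.n_used}\n"
        f"n_excluded    : {fit.n_excluded}\n"
        f"excluded_ids  : {', '.join(fit.excluded_ids)}\n"
    )
    manifest["statistics"]["calibration"] = {
        "b1": fit.b1,
        "b2": fit.b2,
        "r2_uncentered": fit.r2_uncentered,
        "r2_adj": fit.r2_adj,
    }
    logger.info("calibration: b1=%.3f b2=%.3f r2_adj=%.3f", fit.b1, fit.b2, fit.r2_adj)

    elbm_table = stage("elbm")(lambda: compute_elbm(kept, fit))
    annotated = stage("attach_fai")(lambda: attach_fai(elbm_table, series))
    annotated.to_csv(out / "elbm.csv", index=False)
    manifest["counts"]["n_elbm_rows"] = len(annotated)

    summary = stage("summaries")(lambda: summarize_by_class(annotated, individuals))
    summary.to_csv(out / "class_summary.csv", index=False)

    gamm = stage("gamm")(
        lambda: fit_gamm(
            annotated,
            individuals,
            baseline_class=config.baseline_class,
            basis_dim=config.basis_dim,
        )
    )
    gamm.coefficient_rows.to_csv(out / "gamm_coefficients.csv", index=False)
    manifest["statistics"]["gamm"] = {
        "smooth_edf": gamm.smooth_summary.edf,
        "smooth_f": gamm.smooth_summary.f_stat,
        "smooth_p": gamm.smooth_summary.p_value,
        "random_intercept_sd": gamm.random_intercept_sd,
        "residual_sd": gamm.residual_sd,
        "r2_adj": gamm.r2_adj,
    }
    logger.info(
        "GAMM: smooth edf=%.2f F=%.2f p=%.2g", gamm.smooth_summary.edf,
        gamm.smooth_summary.f_stat, gamm.smooth_summary.p_value,
    )

    contrasts = stage("contrasts")(
        lambda: pairwise_contrasts(annotated, individuals, basis_dim=config.basis_dim)
    )
    contrasts.rows.to_csv(out / "contrasts.csv", index=False)

    glmm = stage("glmm")(
        lambda: fit_glmm_binary(
            annotated,
            individuals,
            include_interaction=config.glmm_interaction,
            baseline_class=config.baseline_class,
        )
    )
    glmm.coefficient_rows.to_csv(out / "glmm_coefficients.csv", index=False)

    grid = pd.DataFrame(
        [
            {"age_sex_class": c, "fai_label": lab}
            for c in CLASS_ORDER
            if c in set(individuals["age_sex_class"])
            for lab in ("high", "low")
        ]
    )
    predictions = stage("predictions")(lambda: predict_elbm(glmm, grid))
    predictions.to_csv(out / "predictions.csv", index=False)

    if config.make_plots:
        from . import plots

        stage("plots")(
            lambda: (
                plots.plot_elbm_by_fai(annotated, individuals, out / "elbm_by_fai.png"),
                plots.plot_predicted_elbm(predictions, out / "predicted_elbm.png"),
            )
        )

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float) + "\n")
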
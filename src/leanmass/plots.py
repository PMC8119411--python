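"""Standard figures: per-class ELBM~FAI regression lines and binary-FAI
predicted ELBM with standard errors."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .types import CLASS_ORDER

__all__ = ["plot_elbm_by_fai", "plot_predicted_elbm"]

_COLORS = dict(zip(CLASS_ORDER, ("#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e")))


def plot_elbm_by_fai(annotated: pd.DataFrame, individuals: pd.DataFrame, path) -> None:
    """Scatter of ELBM vs FAI with a per-class least-squares line."""
    class_of = dict(zip(individuals["individual_id"], individuals["age_sex_class"]))
    work = annotated.assign(age_sex_class=annotated["individual_id"].map(class_of))
    fig, ax = plt.subplots(figsize=(7, 5))
    for cls in CLASS_ORDER:
        sub = work[work["age_sex_class"] == cls]
        if len(sub) < 2:
            continue
        x = sub["fai_percent"].to_numpy(dtype=float)
        y = sub["elbm"].to_numpy(dtype=float)
        ax.scatter(x, y, s=8, alpha=0.3, color=_COLORS[cls])
        if np.ptp(x) > 0:
            slope, intercept = np.polyfit(x, y, 1)
            grid = np.linspace(x.min(), x.max(), 50)
            ax.plot(grid, intercept + slope * grid, color=_COLORS[cls], label=cls)
    ax.set_xlabel("fruit availability index (%)")
    ax.set_ylabel("ELBM (residual creatinine, mg/ml)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_predicted_elbm(predictions: pd.DataFrame, path) -> None:
    """Point-and-error-bar plot of predicted ELBM by class and FAI level."""
    fig, ax = plt.subplots(figsize=(7, 5))
    offsets = {"high": -0.12, "low": 0.12}
    markers = {"high": "o", "low": "s"}
    present = [c for c in CLASS_ORDER if c in set(predictions["age_sex_class"])]
    xpos = {c: i for i, c in enumerate(present)}
    for level in ("high", "low"):
        sub = predictions[predictions["fai_label"] == level]
        x = [xpos[c] + offsets[level] for c in sub["age_sex_class"]]
        ax.errorbar(
            x,
            sub["estimate"],
            yerr=sub["se"],
            fmt=markers[level],
            capsize=3,
            label=f"{level} fruit",
        )
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xticks(range(len(present)))
    ax.set_xticklabels(present, rotation=20, fontsize=8)
    ax.set_ylabel("predicted ELBM (mg/ml)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
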
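import numpy as np
import pandas as pd
import pytest

from leanmass import elbm as elbm_mod
from leanmass import fai as fai_mod
from leanmass import synthdata as sd
from leanmass.types import CLASS_ORDER


@pytest.fixture(scope="session")
def small_config():
    """A fast five-class generator config (~350 samples, 25 individuals)."""
    return sd.GeneratorConfig(
        seed=11,
        n_individuals_per_class={c: 5 for c in CLASS_ORDER},
        samples_per_individual=14,
        n_months=12,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(samples, truth, individuals_frame, fai_series) from the generator."""
    pop = sd.make_population(small_config)
    phen = sd.simulate_phenology(
        400,
        small_config.n_months,
        sd.default_fruiting_probs(small_config.n_months),
        seed=small_config.seed,
    )
    series = fai_mod.fai_series_from_phenology(phen)
    samples, truth = sd.simulate_samples(pop, series, small_config)
    return samples, truth, sd.population_frame(pop), series


@pytest.fixture(scope="session")
def small_elbm(small_dataset):
    """Annotated ELBM table + individuals frame from the small dataset."""
    samples, _, individuals, series = small_dataset
    kept, excluded = elbm_mod.filter_dilute(samples)
    fit = elbm_mod.fit_calibration(kept, excluded=excluded)
    table = fai_mod.attach_fai(elbm_mod.compute_elbm(kept, fit), series)
    return table, individuals


def normal_equations_oracle(sg, creatinine):
    """Independent through-origin solve: assemble the 2x2 normal equations
    by hand and solve them directly. Used as the reference for the
    calibration fit; shares no code with the implementation path."""
    x = np.asarray(sg, dtype=float) - 1.0
    x2 = x * x
    y = np.asarray(creatinine, dtype=float)
    a11, a12, a22 = float(x @ x), float(x @ x2), float(x2 @ x2)
    r1, r2 = float(x @ y), float(x2 @ y)
    det = a11 * a22 - a12 * a12
    b1 = (a22 * r1 - a12 * r2) / det
    b2 = (a11 * r2 - a12 * r1) / det
    return b1, b2


def make_samples_frame(sg, creatinine, individual_id="A"):
    """Minimal valid samples table from raw SG / creatinine arrays."""
    sg = np.asarray(sg, dtype=float)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(len(sg))],
            "individual_id": individual_id,
            "date": pd.to_datetime("2015-03-17"),
            "specific_gravity": sg,
            "creatinine_mg_ml": np.asarray(creatinine, dtype=float),
        }
    )
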
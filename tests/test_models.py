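import itertools

import numpy as np
import pandas as pd
import pytest

from leanmass import models as mo
from leanmass.errors import ModelSpecError
from leanmass.fai import FAISeries, binarize_fai
from leanmass.types import CLASS_ORDER


def balanced_table(class_values, per_class=8, months=("2015-01", "2015-02")):
    """One individual per row-group fixture builder: each class gets
    ``per_class`` individuals with one sample each, value per class."""
    rows = []
    sid = 0
    for cls, value in class_values.items():
        for i in range(per_class):
            sid += 1
            month = months[sid % len(months)]
            rows.append(
                {
                    "sample_id": f"S{sid:04d}",
                    "individual_id": f"{cls[:2]}{i:02d}",
                    "date": pd.Timestamp(month + "-15"),
                    "month": month,
                    "elbm": value if np.isscalar(value) else value[i],
                }
            )
    table = pd.DataFrame(rows)
    individuals = (
        table[["individual_id"]]
        .drop_duplicates()
        .assign(age_sex_class=lambda d: d["individual_id"].str[:2].map(
            {c[:2]: c for c in class_values}
        ))
    )
    return table, individuals


@pytest.fixture(scope="module")
def fitted_gamm(small_elbm):
    table, individuals = small_elbm
    return mo.fit_gamm(table, individuals)


class TestFitGamm:
    def test_degenerate_constant_response(self):
        table, individuals = balanced_table({"adult_female": 0.0, "flanged_male": 0.0})
        table["fai_percent"] = 5.0
        res = mo.fit_gamm(table, individuals)
        assert (res.coefficient_rows["estimate"] == 0).all()
        assert res.random_intercept_sd == 0.0
        assert res.smooth_summary.edf == 1.0

    def test_two_class_closed_form_ols(self):
        # One sample per individual and no smooth: baseline intercept is
        # the class-1 mean; the class-2 coefficient is the mean difference.
        rng = np.random.default_rng(5)
        values_a = rng.normal(0.0, 0.3, 10)
        values_b = rng.normal(0.4, 0.3, 10)
        table, individuals = balanced_table(
            {"adult_female": values_a, "flanged_male": values_b}, per_class=10
        )
        res = mo.fit_gamm(table, individuals, smooth=False)
        co = res.coefficient_rows.set_index("term")["estimate"]
        assert co["intercept"] == pytest.approx(values_a.mean(), abs=1e-8)
        assert co["class[flanged_male]"] == pytest.approx(
            values_b.mean() - values_a.mean(), abs=1e-8
        )

    def test_single_class_rejected(self):
        table, individuals = balanced_table({"adult_female": [0.1] * 8})
        table["fai_percent"] = np.linspace(1, 10, len(table))
        with pytest.raises(ModelSpecError):
            mo.fit_gamm(table, individuals)

    def test_smooth_detects_fai_effect(self, fitted_gamm):
        assert fitted_gamm.smooth_summary.p_value < 0.01
        assert fitted_gamm.smooth_summary.edf >= 1.0

    def test_class_signs_on_synthetic_defaults(self, fitted_gamm):
        co = fitted_gamm.coefficient_rows.set_index("term")["estimate"]
        assert co["class[flanged_male]"] > 0
        assert co["class[unflanged_male]"] > 0
        assert co["class[adolescent]"] < 0
        assert co["class[dependent]"] < 0

    def test_smooth_nondecreasing_central_range(self, small_elbm, fitted_gamm):
        table, _ = small_elbm
        fai = table["fai_percent"]
        lo, hi = fai.quantile([0.1, 0.9])
        grid = np.linspace(lo, hi, 50)
        pred = fitted_gamm.predict_smooth(grid)["estimate"].to_numpy()
        assert np.all(np.diff(pred) >= -1e-9)

    def test_se_positive_and_row_shape(self, fitted_gamm):
        rows = fitted_gamm.coefficient_rows
        assert (rows["se"] > 0).all()
        assert list(rows["term"]) == ["intercept"] + [
            f"class[{c}]" for c in CLASS_ORDER if c != "adult_female"
        ]


class TestRelevelContrasts:
    def test_loglik_and_fitted_invariant(self, small_elbm):
        table, individuals = small_elbm
        fits = [
            mo.fit_gamm(table, individuals, baseline_class=c) for c in CLASS_ORDER
        ]
        base = fits[0]
        for other in fits[1:]:
            assert other.loglik == pytest.approx(base.loglik, abs=1e-6)
            np.testing.assert_allclose(other.fitted, base.fitted, atol=1e-6)

    def test_antisymmetry(self, small_elbm):
        table, individuals = small_elbm
        contrasts = mo.pairwise_contrasts(table, individuals, dedupe=False)
        rows = contrasts.rows_all.set_index(["baseline_class", "other_class"])
        est = rows["estimate"]
        assert est[("adult_female", "flanged_male")] == pytest.approx(
            -est[("flanged_male", "adult_female")], abs=1e-6
        )
        for a, b in itertools.combinations(CLASS_ORDER, 2):
            assert est[(a, b)] == pytest.approx(-est[(b, a)], abs=1e-6)

    def test_identical_classes_contrast_zero(self):
        values = list(np.linspace(-0.3, 0.3, 8))
        table, individuals = balanced_table(
            {"adult_female": values, "flanged_male": values}
        )
        table["fai_percent"] = np.tile(np.linspace(1, 10, 8), 2)
        contrasts = mo.pairwise_contrasts(table, individuals, smooth=False)
        row = contrasts.rows.iloc[0]
        assert row["estimate"] == pytest.approx(0.0, abs=1e-8)
        assert row["p_value"] == pytest.approx(1.0, abs=1e-6)

    def test_unique_pair_count(self, small_elbm):
        table, individuals = small_elbm
        contrasts = mo.pairwise_contrasts(table, individuals)
        assert len(contrasts.rows) == 10  # 5 * 4 / 2
        assert len(contrasts.rows_all) == 20
        pairs = set(map(tuple, contrasts.rows[["baseline_class", "other_class"]].values))
        assert len(pairs) == 10


class TestGlmmBinary:
    def test_no_fai_difference_gives_zero_coefficient(self):
        # every individual has one high and one low sample with the SAME
        # ELBM value, so the low-FAI effect is exactly zero
        rng = np.random.default_rng(8)
        rows = []
        sid = 0
        for k in range(10):
            cls = "adult_female" if k < 5 else "flanged_male"
            value = float(rng.normal(0.0, 0.3))
            for label in ("high", "low"):
                sid += 1
                rows.append(
                    {
                        "sample_id": f"S{sid:04d}",
                        "individual_id": f"I{k:02d}",
                        "elbm": value,
                        "fai_label": label,
                    }
                )
        table = pd.DataFrame(rows)
        individuals = pd.DataFrame(
            {
                "individual_id": [f"I{k:02d}" for k in range(10)],
                "age_sex_class": ["adult_female"] * 5 + ["flanged_male"] * 5,
            }
        )
        res = mo.fit_glmm_binary(table, individuals)
        co = res.coefficient_rows.set_index("term")
        assert co.loc["fai[low]", "estimate"] == pytest.approx(0.0, abs=1e-7)

    def test_low_fai_negative_on_synthetic(self, small_elbm):
        table, individuals = small_elbm
        res = mo.fit_glmm_binary(table, individuals)
        co = res.coefficient_rows.set_index("term")
        assert co.loc["fai[low]", "estimate"] < 0
        assert co.loc["fai[low]", "p_value"] < 0.05

    def test_single_fai_level_rejected(self, small_elbm):
        table, individuals = small_elbm
        only_high = table.assign(fai_label="high")
        with pytest.raises(ModelSpecError):
            mo.fit_glmm_binary(only_high, individuals)

    def test_interaction_structure(self, small_elbm):
        table, individuals = small_elbm
        grid = pd.DataFrame(
            [
                {"age_sex_class": c, "fai_label": lab}
                for c in CLASS_ORDER
                for lab in ("high", "low")
            ]
        )
        main = mo.fit_glmm_binary(table, individuals, include_interaction=False)
        pred = mo.predict_elbm(main, grid)
        diffs = (
            pred.pivot(index="age_sex_class", columns="fai_label", values="estimate")
            .eval("low - high")
            .to_numpy()
        )
        np.testing.assert_allclose(diffs, diffs[0], atol=1e-9)

        inter = mo.fit_glmm_binary(table, individuals, include_interaction=True)
        pred_i = mo.predict_elbm(inter, grid)
        diffs_i = (
            pred_i.pivot(index="age_sex_class", columns="fai_label", values="estimate")
            .eval("low - high")
            .to_numpy()
        )
        assert np.ptp(diffs_i) > 1e-6  # per-class gaps are free


class TestPredictElbm:
    def test_grid_size(self, small_elbm):
        table, individuals = small_elbm
        res = mo.fit_glmm_binary(table, individuals)
        grid = pd.DataFrame(
            [
                {"age_sex_class": c, "fai_label": lab}
                for c in CLASS_ORDER
                for lab in ("high", "low")
            ]
        )
        pred = mo.predict_elbm(res, grid)
        assert len(pred) == 10
        assert (pred["se"] > 0).all()

    def test_baseline_reference_equals_intercept(self, small_elbm):
        table, individuals = small_elbm
        res = mo.fit_glmm_binary(table, individuals)
        grid = pd.DataFrame([{"age_sex_class": "adult_female", "fai_label": "high"}])
        pred = mo.predict_elbm(res, grid)
        assert pred.loc[0, "estimate"] == pytest.approx(
            res.coefficient("intercept")["estimate"], abs=1e-12
        )

    def test_high_low_difference_matches_design_oracle(self, small_elbm):
        table, individuals = small_elbm
        res = mo.fit_glmm_binary(table, individuals, include_interaction=True)
        grid = pd.DataFrame(
            [
                {"age_sex_class": "adolescent", "fai_label": "high"},
                {"age_sex_class": "adolescent", "fai_label": "low"},
            ]
        )
        pred = mo.predict_elbm(res, grid)
        co = res.coefficient_rows.set_index("term")["estimate"]
        # hand-assembled design-matrix difference: fai[low] + interaction
        expected = co["fai[low]"] + co["fai[low]:class[adolescent]"]
        assert pred.loc[1, "estimate"] - pred.loc[0, "estimate"] == pytest.approx(
            expected, abs=1e-10
        )

    def test_unseen_level_rejected(self, small_elbm):
        table, individuals = small_elbm
        res = mo.fit_glmm_binary(table, individuals)
        with pytest.raises(ModelSpecError):
            mo.predict_elbm(
                res, pd.DataFrame([{"age_sex_class": "gorilla", "fai_label": "high"}])
            )


class TestFaiSeriesHelpers:
    def test_attach_through_fit_gamm(self, small_dataset, small_elbm):
        # fit_gamm attaches FAI itself when given the series
        samples, _, individuals, series = small_dataset
        table, _ = small_elbm
        bare = table.drop(columns=["fai_percent", "fai_label"])
        res = mo.fit_gamm(bare, individuals, fai_series=series)
        assert res.smooth_summary is not None

    def test_series_roundtrip(self):
        series = binarize_fai(FAISeries(entries={"2015-01": 4.0, "2015-02": 9.0}))
        again = FAISeries.from_frame(series.to_frame())
        assert again.entries == series.entries
        assert again.labels == series.labels
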
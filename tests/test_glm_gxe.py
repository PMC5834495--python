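"""Nested GLM ladder, F-statistics, composite phenotype, logistic arm."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from bnbmla.cohort_data import from_dataframe
from bnbmla.glm_gxe import (
    GlmModelSpec,
    build_composite_phenotype,
    build_design_matrix,
    compare_nested,
    fit_glm,
    logistic_main_effects,
    run_model_ladder,
)
from bnbmla.synthetic_cohort import gxe_config, null_config, simulate_cohort
from .conftest import make_cohort_frame


class TestComposite:
    def test_monotone_in_components(self):
        frame = make_cohort_frame(40, seed=0)
        frame.loc[0, ["dep", "bsi_dep", "bsi_anx"]] = [0, 0.0, 0.0]
        frame.loc[1, ["dep", "bsi_dep", "bsi_anx"]] = [1, 3.5, 3.5]
        cohort = from_dataframe(frame)
        y = build_composite_phenotype(cohort)
        assert y[0] == y.min()
        assert y[1] == y.max()

    def test_identical_subjects_equal_scores(self):
        frame = make_cohort_frame(10, seed=1)
        frame.loc[3, ["dep", "bsi_dep", "bsi_anx"]] = frame.loc[
            7, ["dep", "bsi_dep", "bsi_anx"]
        ].values
        y = build_composite_phenotype(from_dataframe(frame))
        assert y[3] == pytest.approx(y[7])

    def test_correlates_with_each_component(self, gxe_cohort):
        y = build_composite_phenotype(gxe_cohort)
        assert spearmanr(y, gxe_cohort.frame["dep"]).statistic > 0
        assert spearmanr(y, gxe_cohort.frame["bsi_dep"]).statistic > 0
        assert spearmanr(y, gxe_cohort.frame["bsi_anx"]).statistic > 0

    def test_zero_variance_component_handled(self):
        frame = make_cohort_frame(30, seed=2)
        frame["dep"] = 1
        y = build_composite_phenotype(from_dataframe(frame))
        assert np.isfinite(y).all()


class TestFitGlm:
    def test_constant_response_r2_zero(self):
        frame = make_cohort_frame(50, seed=3)
        frame[["dep", "bsi_dep", "bsi_anx"]] = 0
        frame["dep"] = [0, 1] * 25  # binary response with variance
        fit = fit_glm(from_dataframe(frame), GlmModelSpec(response="bsi_dep"))
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_response_r2_one(self):
        # response built to be an exact linear function of the RLE count
        frame = make_cohort_frame(60, seed=4)
        frame["rle_count"] = np.tile([0, 1, 2, 3, 4, 5], 10)
        cohort = from_dataframe(frame)
        spec = GlmModelSpec(
            response="composite", terms=("covariates", "rle_main"), rle_coding="continuous"
        )
        y = cohort.frame["rle_count"].to_numpy(dtype=float)
        X, _ = build_design_matrix(cohort, spec)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert ((X @ coef - y) ** 2).sum() == pytest.approx(0.0, abs=1e-18)

    def test_coefficients_match_normal_equations(self, small_cohort):
        spec = GlmModelSpec(terms=("covariates", "rle_main"))
        fit = fit_glm(small_cohort, spec)
        X, _ = build_design_matrix(small_cohort, spec)
        y = build_composite_phenotype(small_cohort)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.coef == pytest.approx(beta, abs=1e-8)
        assert fit.sse == pytest.approx(((y - X @ beta) ** 2).sum())

    def test_f_matches_statsmodels_anova(self, gxe_cohort):
        import statsmodels.api as sm

        small_spec = GlmModelSpec(terms=("covariates", "rle_main"))
        big_spec = GlmModelSpec(terms=("covariates", "rle_main", "genetic_main"))
        cmp_ = compare_nested(fit_glm(gxe_cohort, small_spec), fit_glm(gxe_cohort, big_spec))
        y = build_composite_phenotype(gxe_cohort)
        Xs, _ = build_design_matrix(gxe_cohort, small_spec)
        Xb, _ = build_design_matrix(gxe_cohort, big_spec)
        ref = sm.OLS(y, Xb).fit().compare_f_test(sm.OLS(y, Xs).fit())
        assert cmp_.f_stat == pytest.approx(ref[0], rel=1e-10)
        assert cmp_.p_value == pytest.approx(ref[1], rel=1e-8)
        assert cmp_.df_num == int(ref[2])


class TestCompareNested:
    def test_equal_sse_gives_zero_f(self, small_cohort):
        fit1 = fit_glm(small_cohort, GlmModelSpec(terms=("covariates", "rle_main")))
        clone = fit_glm(
            small_cohort,
            GlmModelSpec(terms=("covariates", "rle_main", "genetic_main")),
        )
        clone.sse = fit1.sse
        assert compare_nested(fit1, clone).f_stat >= 0.0

    def test_non_nested_rejected(self, small_cohort):
        fit1 = fit_glm(small_cohort, GlmModelSpec(terms=("covariates", "rle_main")))
        with pytest.raises(ValueError):
            compare_nested(fit1, fit1)

    def test_null_f_mean_near_one(self):
        # adding a pure-noise term block: E[F] ~ df_den / (df_den - 2) ~ 1
        rng = np.random.default_rng(5)
        fs = []
        for seed in range(200):
            cohort = simulate_cohort(null_config(n_subjects=400, seed=seed)).cohort
            lad = run_model_ladder(cohort)
            fs.append(lad.m2_vs_m1.f_stat)
        assert np.mean(fs) == pytest.approx(1.0, abs=0.15)


class TestModelLadder:
    def test_r2_monotone_along_ladder(self, gxe_cohort):
        lad = run_model_ladder(gxe_cohort)
        r2 = lad.variance_table.set_index("model")["r2_total"]
        assert (
            r2["Model-1 (RLE)"]
            <= r2["Model-2 (RLE + genetic mains)"]
            <= r2["Model-3 (+ GxE interactions)"]
        )
        assert (lad.variance_table["r2_beyond_covariates"] >= -1e-12).all()

    def test_rle_effect_detected(self, gxe_cohort):
        lad = run_model_ladder(gxe_cohort)
        assert lad.m1_vs_null.p_value < 1e-5

    def test_interaction_detected_on_gxe_cohort(self, gxe_cohort):
        lad = run_model_ladder(gxe_cohort)
        assert lad.m3_vs_m2.df_num == 28  # 7 SNPs x 2 genotype df x 2 RLE df

    def test_continuous_rle_coding_changes_df(self, gxe_cohort):
        lad = run_model_ladder(gxe_cohort, rle_coding="continuous")
        assert lad.m1_vs_null.df_num == 1
        assert lad.m3_vs_m2.df_num == 14  # 7 SNPs x 2 genotype df x 1 RLE df

    def test_frame_schema(self, gxe_cohort):
        frame = run_model_ladder(gxe_cohort).to_frame()
        assert list(frame.columns) == [
            "comparison", "df1", "df2", "F", "p_value", "r2_small", "r2_big", "delta_r2"
        ]


class TestLogistic:
    def test_null_odds_ratios_near_one(self):
        cohort = simulate_cohort(null_config(n_subjects=20_000, seed=6)).cohort
        effects = logistic_main_effects(cohort)
        assert len(effects) == 7
        for e in effects:
            assert e.odds_ratio == pytest.approx(1.0, abs=0.08)

    def test_two_by_two_collapse_matches_cross_product(self):
        # dominant-coded 2x2 sanity check on a hand-built table with a real
        # genotype effect and no covariate structure
        rng = np.random.default_rng(7)
        n = 4000
        frame = make_cohort_frame(n, seed=7)
        g = rng.integers(0, 2, n)  # carrier yes/no
        frame["rs6265"] = np.where(g == 1, "AG", "GG")
        p = np.where(g == 1, 0.6, 0.4)
        frame["dep"] = (rng.random(n) < p).astype(int)
        # covariates randomized independently of the outcome: collapsing
        # over them leaves the marginal odds ratio intact
        frame["age"] = rng.uniform(20, 60, n).round(1)
        frame["sex"] = rng.choice(["male", "female"], n)
        frame["population"] = rng.choice(["BUD", "MAN"], n)
        # cross-product ratio from the collapsed 2x2 table
        cohort_frame = frame.copy()
        a = ((g == 1) & (frame["dep"] == 1)).sum()
        b = ((g == 1) & (frame["dep"] == 0)).sum()
        c = ((g == 0) & (frame["dep"] == 1)).sum()
        d = ((g == 0) & (frame["dep"] == 0)).sum()
        expected_or = (a * d) / (b * c)
        import statsmodels.api as sm

        X = sm.add_constant(g.astype(float))
        fit = sm.Logit(frame["dep"].to_numpy(dtype=float), X).fit(disp=False)
        assert np.exp(fit.params[1]) == pytest.approx(expected_or, rel=1e-6)
        # the module's additive fit on the same data agrees to first order
        effects = {e.snp: e for e in logistic_main_effects(from_dataframe(cohort_frame))}
        assert effects["rs6265"].odds_ratio == pytest.approx(expected_or, rel=0.05)

    def test_gxe_generator_shows_no_strong_mains(self, gxe_cohort):
        effects = logistic_main_effects(gxe_cohort)
        # interaction-only regime: additive main-effect ORs stay modest
        for e in effects:
            assert 0.8 < e.odds_ratio < 1.35
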
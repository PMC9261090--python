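"""REML engine: exact limits, closed-form oracles, invariances, lmer cross-check."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from esm_affect.affect_scoring import ValidationError
from esm_affect.design_builder import (
    ModelDataset,
    RandomStructure,
    RandomTerm,
    build_activation_design,
    build_ambivalence_design,
    build_category_design,
)
from esm_affect.lmm_engine import (
    approximate_df,
    bonferroni_adjust,
    conditional_effects,
    contrast_test,
    fit_lmm,
    wald_f_test,
)
from esm_affect.design_builder import attach_moderator
from esm_affect.synthetic_data import GeneratorParams, simulate_dataset


def one_way_dataset(m=8, k=6, sigma_u=1.3, sigma_e=0.8, mu=4.0, seed=0):
    """Balanced one-way random-intercept data with known ANOVA estimators."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sigma_u, m)
    rows = []
    for i in range(m):
        for _ in range(k):
            rows.append({"participant_id": f"s{i}", "y": mu + u[i] + rng.normal(0, sigma_e)})
    data = pd.DataFrame(rows)
    return ModelDataset(
        outcome="y",
        data=data,
        fixed_effects=[],
        random=RandomStructure([RandomTerm("participant_id", None, "subject")]),
    )


class TestClosedFormOracles:
    def test_balanced_one_way_matches_anova_estimators(self):
        m, k = 8, 6
        ds = one_way_dataset(m, k, seed=4)
        y = ds.data["y"].to_numpy()
        groups = ds.data["participant_id"].to_numpy()
        means = pd.Series(y).groupby(groups).mean().to_numpy()
        grand = y.mean()
        msb = k * ((means - grand) ** 2).sum() / (m - 1)
        msw = sum(((y[groups == g] - mg) ** 2).sum() for g, mg in zip(sorted(set(groups)), means)) / (
            m * (k - 1)
        )
        fit = fit_lmm(ds)
        # balanced one-way REML equals the ANOVA method-of-moments estimators
        assert fit.sigma**2 == pytest.approx(msw, rel=1e-4)
        assert fit.random_effects.loc["subject", "variance"] == pytest.approx(
            (msb - msw) / k, rel=1e-4
        )
        assert fit.coef("intercept") == pytest.approx(grand, abs=1e-8)
        # the grand mean is a mean of m iid subject means
        assert fit.fixed.loc["intercept", "se"] == pytest.approx(np.sqrt(msb / (m * k)), rel=1e-4)
        assert fit.fixed.loc["intercept", "df"] == pytest.approx(m - 1, rel=0.05)

    def test_balanced_two_condition_fixed_effects_equal_cell_means(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(6):
            for j, cond in enumerate(["a", "b"] * 2):
                rows.append(
                    {
                        "participant_id": f"s{i}",
                        "stimulus_id": f"t{j}",
                        "x": 1.0 if cond == "b" else 0.0,
                        "y": 2.0 + (1.5 if cond == "b" else 0.0) + rng.normal(0, 0.5),
                    }
                )
        data = pd.DataFrame(rows)
        ds = ModelDataset(
            outcome="y",
            data=data,
            fixed_effects=["x"],
            random=RandomStructure(
                [
                    RandomTerm("participant_id", None, "subject"),
                    RandomTerm("stimulus_id", None, "stimulus"),
                ]
            ),
        )
        fit = fit_lmm(ds)
        mean_a = data.loc[data.x == 0, "y"].mean()
        mean_b = data.loc[data.x == 1, "y"].mean()
        # balance makes GLS coincide with the cell means for the fixed part
        assert fit.coef("intercept") == pytest.approx(mean_a, abs=1e-6)
        assert fit.coef("x") == pytest.approx(mean_b - mean_a, abs=1e-6)


class TestOLSLimit:
    @pytest.mark.parametrize("family", ["category", "ambivalence", "activation"])
    def test_no_random_effects_equals_least_squares(self, small_study, family):
        _, _, _, trials = small_study
        if family == "category":
            ds = build_category_design(trials, "positivity")
        elif family == "ambivalence":
            ds = build_ambivalence_design(trials)
        else:
            ds = build_activation_design(trials, seed=0)
        fit = fit_lmm(ds, random=RandomStructure())
        X = np.column_stack(
            [np.ones(len(ds.data))] + [ds.data[c].to_numpy(float) for c in ds.fixed_effects]
        )
        y = ds.data[ds.outcome].to_numpy(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.fixed["estimate"].to_numpy(), beta, atol=1e-6)
        assert (fit.fixed["df"] == len(y) - X.shape[1]).all()  # exact OLS df


class TestInvariances:
    def test_row_permutation_leaves_estimates_unchanged(self, small_study):
        _, _, _, trials = small_study
        ds = build_activation_design(trials, seed=0)
        fit1 = fit_lmm(ds, compute_df=False)
        shuffled = ModelDataset(
            outcome=ds.outcome,
            data=ds.data.sample(frac=1.0, random_state=3).reset_index(drop=True),
            fixed_effects=ds.fixed_effects,
            random=ds.random,
            factors=ds.factors,
        )
        fit2 = fit_lmm(shuffled, compute_df=False)
        np.testing.assert_allclose(
            fit1.fixed["estimate"], fit2.fixed["estimate"], rtol=0, atol=1e-10
        )

    def test_outcome_shift_moves_intercept_only(self, small_study):
        _, _, _, trials = small_study
        ds = build_activation_design(trials, seed=0)
        fit1 = fit_lmm(ds, compute_df=False)
        shifted = ds.data.copy()
        shifted["emotional_activation"] = shifted["emotional_activation"] + 10.0
        ds2 = ModelDataset(
            outcome=ds.outcome, data=shifted, fixed_effects=ds.fixed_effects,
            random=ds.random, factors=ds.factors,
        )
        fit2 = fit_lmm(ds2, compute_df=False)
        assert fit2.coef("intercept") == pytest.approx(fit1.coef("intercept") + 10.0, abs=1e-5)
        np.testing.assert_allclose(
            fit1.fixed["estimate"].iloc[1:], fit2.fixed["estimate"].iloc[1:], atol=1e-5
        )
        np.testing.assert_allclose(
            fit1.random_effects["variance"], fit2.random_effects["variance"], rtol=1e-3, atol=1e-6
        )

    def test_predictor_rescaling_leaves_standardized_beta_unchanged(self, small_study):
        _, _, _, trials = small_study
        ds = build_category_design(trials, "positivity")
        fit1 = fit_lmm(ds, compute_df=False)
        scaled = ds.data.copy()
        scaled["cat_pleasant"] = scaled["cat_pleasant"] * 4.0
        # rescaling a column is a pure reparameterization of the same model
        ds2 = ModelDataset(
            outcome=ds.outcome, data=scaled, fixed_effects=ds.fixed_effects,
            random=ds.random, factors=ds.factors,
        )
        fit2 = fit_lmm(ds2, compute_df=False)
        assert fit2.coef("cat_pleasant") == pytest.approx(fit1.coef("cat_pleasant") / 4.0, rel=1e-2)
        assert fit2.fixed.loc["cat_pleasant", "beta"] == pytest.approx(
            fit1.fixed.loc["cat_pleasant", "beta"], rel=1e-2
        )


class TestSatterthwaite:
    def test_df_positive_and_bounded(self, small_study):
        _, _, _, trials = small_study
        fit = fit_lmm(build_activation_design(trials, seed=0))
        assert ((fit.fixed["df"] > 0) & (fit.fixed["df"] <= fit.n_obs - 1)).all()

    def test_contrast_dimension_checked(self, small_study):
        _, _, _, trials = small_study
        fit = fit_lmm(build_activation_design(trials, seed=0))
        with pytest.raises(ValidationError):
            approximate_df(fit, np.ones(fit.n_fixed + 2))

    def test_single_column_wald_f_equals_squared_t(self, small_study):
        _, _, _, trials = small_study
        fit = fit_lmm(build_activation_design(trials, seed=0))
        res = wald_f_test(fit, ["function_pos"])
        assert res["F"] == pytest.approx(fit.fixed.loc["function_pos", "t"] ** 2, rel=1e-8)
        assert res["df2"] == pytest.approx(fit.fixed.loc["function_pos", "df"], rel=0.05)


class TestAgainstLmer:
    def test_crossed_correlated_model_matches_lmerTest(self, small_study, tmp_path):
        """Independent oracle: lme4/lmerTest on the identical dataset."""
        _, _, _, trials = small_study
        ds = build_activation_design(trials, seed=1)
        fit = fit_lmm(ds)
        csv = tmp_path / "design.csv"
        ds.data.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            m <- lmer(emotional_activation ~ function_pos + arousal + fpos_x_arousal +
                      (0 + f_eff + f_eff_x_arousal | participant_id) + (1 | stimulus_id),
                      data = d, REML = TRUE,
                      control = lmerControl(optimizer = "bobyqa",
                                            optCtrl = list(maxfun = 100000)))
            co <- coef(summary(m))
            vc <- as.data.frame(VarCorr(m))
            write.csv(co, "{tmp_path}/fixed.csv")
            write.csv(vc, "{tmp_path}/vc.csv", row.names = FALSE)
            """
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True, timeout=300)
        rfix = pd.read_csv(tmp_path / "fixed.csv", index_col=0)
        rfix.index = ["intercept", "function_pos", "arousal", "fpos_x_arousal"]
        np.testing.assert_allclose(
            fit.fixed["estimate"], rfix["Estimate"], rtol=1e-3, atol=1e-3
        )
        np.testing.assert_allclose(
            fit.fixed["se"], rfix["Std. Error"], rtol=1e-2
        )
        np.testing.assert_allclose(fit.fixed["df"], rfix["df"], rtol=0.03)
        rvc = pd.read_csv(tmp_path / "vc.csv")
        def r_var(grp, var1):
            row = rvc[(rvc["grp"].str.startswith(grp)) & (rvc["var1"].fillna("") == var1)]
            return float(row["vcov"].iloc[0])
        assert fit.random_effects.loc["subject_offset", "variance"] == pytest.approx(
            r_var("participant_id", "f_eff"), rel=0.05, abs=1e-3
        )
        assert fit.random_effects.loc["subject_bias", "variance"] == pytest.approx(
            r_var("participant_id", "f_eff_x_arousal"), rel=0.05, abs=1e-3
        )
        assert fit.random_effects.loc["stimulus_intercept", "variance"] == pytest.approx(
            r_var("stimulus_id", "(Intercept)"), rel=0.05, abs=1e-3
        )
        assert fit.sigma**2 == pytest.approx(r_var("Residual", ""), rel=0.02)


@pytest.fixture(scope="module")
def moderated_fit(small_study):
    _, participants, _, trials = small_study
    ds = attach_moderator(build_category_design(trials, "positivity"), "cape_negative", participants)
    return fit_lmm(ds)


class TestConditionalEffects:
    def test_gate_suppresses_and_force_overrides(self, moderated_fit):
        # trend_p = 0 can never be reached, so the table is suppressed ...
        assert conditional_effects(moderated_fit, factor="category", trend_p=0.0) is None
        # ... while force always yields one row per category level
        tab = conditional_effects(moderated_fit, factor="category", trend_p=0.0, force=True)
        assert list(tab.index) == ["reference", "cat_pleasant", "cat_unpleasant"]
        assert {"estimate", "se", "df", "t", "p", "beta"} <= set(tab.columns)

    def test_slopes_are_sum_of_main_and_interaction(self, moderated_fit):
        tab = conditional_effects(moderated_fit, factor="category", trend_p=1.0)
        b = moderated_fit.fixed["estimate"]
        assert tab.loc["reference", "estimate"] == pytest.approx(b["mod"], abs=1e-10)
        assert tab.loc["cat_pleasant", "estimate"] == pytest.approx(
            b["mod"] + b["cat_pleasant_x_mod"], abs=1e-10
        )

    def test_missing_interaction_rejected(self, small_study):
        _, _, _, trials = small_study
        fit = fit_lmm(build_category_design(trials, "positivity"), compute_df=False)
        with pytest.raises(ValidationError):
            conditional_effects(fit, factor="category")


class TestBonferroni:
    def test_examples_and_cap(self):
        np.testing.assert_allclose(bonferroni_adjust([0.01], 4), [0.04])
        np.testing.assert_allclose(bonferroni_adjust([0.4], 4), [1.0])
        np.testing.assert_allclose(bonferroni_adjust([0.2, 0.03], 2), [0.4, 0.06])
        np.testing.assert_allclose(bonferroni_adjust([0.123], 1), [0.123])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_adjust([1.2], 2)
        with pytest.raises(ValidationError):
            bonferroni_adjust([0.01, 0.02, 0.03], 2)
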
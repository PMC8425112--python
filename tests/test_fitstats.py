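"""GLM fitting, interaction tests and BIC against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import snpxe
from snpxe import (
    Direction,
    InheritanceMode,
    ModelStructure,
    PatternSpec,
    bic,
    fit_glm,
    fit_pattern,
    interaction_test,
    parse_label,
)
from snpxe.fitstats import _reduced_design


# -- independent oracles: hand-rolled IRLS / normal equations --------------

def irls_logistic(X, y, iters=60):
    """Newton-Raphson logistic MLE written from the score equations."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        beta = beta + np.linalg.solve((X * W[:, None]).T @ X, X.T @ (y - mu))
    return beta


def normal_equations(X, y):
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFitGlm:
    def test_saturated_2x2_matches_cross_product_ratio(self, toy_counts_2x2):
        design, y = toy_counts_2x2
        fit = fit_glm(design, y, "logistic")
        assert fit.converged
        # OR = (10*45)/(40*5) = 2.25
        assert np.exp(fit.params["x"]) == pytest.approx(2.25, abs=1e-6)
        assert fit.params["x"] == pytest.approx(np.log(2.25), abs=1e-6)

    def test_intercept_only_log_likelihood_closed_form(self):
        y = np.repeat([1.0, 0.0], [30, 70])
        design = pd.DataFrame({"const": np.ones(100)})
        fit = fit_glm(design, y, "logistic")
        # MLE p-hat = 0.30 -> llf = 30 ln 0.3 + 70 ln 0.7
        assert fit.log_likelihood == pytest.approx(30 * np.log(0.3) + 70 * np.log(0.7), abs=1e-8)
        assert fit.log_likelihood == pytest.approx(-61.08643, abs=1e-5)
        # BIC = -2*llf + 1*ln(100)
        assert bic(fit) == pytest.approx(126.77803, abs=1e-5)

    def test_perfect_separation_flagged_not_raised(self):
        x = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        y = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        design = pd.DataFrame({"const": 1.0, "x": x})
        fit = fit_glm(design, y, "logistic")
        assert not fit.converged

    def test_logistic_agrees_with_irls_oracle(self, rng):
        n = 20
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 3, n)])
        y = (rng.random(n) < 0.5).astype(float)
        design = pd.DataFrame(X, columns=["const", "z", "g"])
        fit = fit_glm(design, y, "logistic")
        np.testing.assert_allclose(fit.params.to_numpy(), irls_logistic(X, y), atol=1e-6)

    def test_linear_agrees_with_normal_equations(self, rng):
        n = 20
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 1.0 + 2.0 * X[:, 1] + rng.normal(size=n)
        design = pd.DataFrame(X, columns=["const", "z"])
        fit = fit_glm(design, y, "linear")
        np.testing.assert_allclose(fit.params.to_numpy(), normal_equations(X, y), atol=1e-6)
        # Gaussian log-likelihood at the MLE variance, variance counted in n_params
        ssr = np.sum((y - X @ fit.params.to_numpy()) ** 2)
        llf = -n / 2 * (np.log(2 * np.pi * ssr / n) + 1)
        assert fit.log_likelihood == pytest.approx(llf, abs=1e-8)
        assert fit.n_params == 3

    def test_non_binary_outcome_rejected_for_logistic(self):
        design = pd.DataFrame({"const": np.ones(4)})
        with pytest.raises(ValueError, match="0/1 outcome"):
            fit_glm(design, np.array([0.0, 1, 2, 1]), "logistic")

    def test_more_params_than_rows_flagged(self):
        design = pd.DataFrame(np.eye(3), columns=list("abc"))
        fit = fit_glm(design, np.array([0.0, 1, 0]), "logistic")
        assert not fit.converged


class TestInteractionTest:
    def test_span_equivalent_full_model_gives_zero_statistic(self, rng):
        """Extra columns inside the reduced model's span -> statistic 0, p = 1."""
        n = 40
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        reduced = pd.DataFrame({"const": 1.0, "x": x})
        full = pd.DataFrame({"const": 1.0, "x": x, "x_flip": 1.0 - x})
        stat, df, p = interaction_test(
            fit_glm(full, y, "linear"), fit_glm(reduced, y, "linear"), "lrt"
        )
        assert stat == pytest.approx(0.0, abs=1e-8)
        assert df == 1
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_chi_square_tail_closed_form(self):
        # chi2(2) survival at 9.21034 is exp(-9.21034/2) ~ 0.010
        assert st.chi2.sf(9.21034, 2) == pytest.approx(np.exp(-9.21034 / 2), rel=1e-12)
        assert st.chi2.sf(9.21034, 2) == pytest.approx(0.010, abs=1e-6)

    def test_non_nested_rejected(self, toy_counts_2x2):
        design, y = toy_counts_2x2
        full = fit_glm(design, y, "logistic")
        with pytest.raises(ValueError, match="nested"):
            interaction_test(full, full, "lrt")

    def test_linear_partial_f_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 60
        X = pd.DataFrame({"const": 1.0, "a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = 0.5 + 0.3 * X["a"] + rng.normal(size=n)
        full = fit_glm(X, y, "linear")
        reduced = fit_glm(X[["const", "a"]], y, "linear")
        stat, df, p = interaction_test(full, reduced, "lrt")
        res_f = sm.OLS(y, X).fit()
        res_r = sm.OLS(y, X[["const", "a"]]).fit()
        f_ref, p_ref, df_ref = res_f.compare_f_test(res_r)
        assert stat == pytest.approx(f_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)
        assert df == df_ref

    def test_wald_and_lrt_agree_on_strong_signal(self, planted_data):
        spec = parse_label("Int_RE_or")
        f_lrt = fit_pattern(planted_data, spec, "snp1", "env_g3", "outcome", test="lrt")
        f_wald = fit_pattern(planted_data, spec, "snp1", "env_g3", "outcome", test="wald")
        assert f_lrt.p_interaction < 1e-6 and f_wald.p_interaction < 1e-6


class TestFitPattern:
    def test_reports_or_with_ci_per_interaction_term(self, planted_data):
        pf = fit_pattern(planted_data, parse_label("Int_RE_or"),
                         "snp1", "env_g3", "outcome")
        assert pf.estimable
        terms = pf.per_term.set_index("term")
        inter = [t for t in terms.index if t.startswith("SNP:")]
        assert len(inter) == 2
        for t in inter:
            assert terms.loc[t, "OR_low"] <= terms.loc[t, "OR"] <= terms.loc[t, "OR_high"]
        # planted ORs 4.3 (level-1 dummy) and 1.8 (level-2 dummy) inside their CIs
        assert terms.loc["SNP:ENV_1vs3", "OR_low"] < 4.3 < terms.loc["SNP:ENV_1vs3", "OR_high"]
        assert terms.loc["SNP:ENV_2vs3", "OR_low"] < 1.8 < terms.loc["SNP:ENV_2vs3", "OR_high"]

    def test_monomorphic_snp_not_estimable(self, null_data):
        data = null_data.copy()
        data["snp_mono"] = 0
        for spec in snpxe.enumerate_patterns("ordinal"):
            pf = fit_pattern(data, spec, "snp_mono", "env_g3", "outcome")
            assert not pf.estimable and pf.bic is None and pf.p_interaction is None

    def test_full_additive_matches_reference_glm(self, null_data):
        """Full_AE_oo coefficients equal a manually assembled statsmodels fit."""
        import statsmodels.api as sm

        pf = fit_pattern(null_data, parse_label("Full_AE_oo"), "snp1", "env_g3", "outcome")
        d = null_data
        X = pd.DataFrame({
            "const": 1.0,
            "S": d["snp1"].astype(float),
            "I2": (d["env_g3"] == 2).astype(float),
            "I3": (d["env_g3"] == 3).astype(float),
        })
        X["SI2"] = X["S"] * X["I2"]
        X["SI3"] = X["S"] * X["I3"]
        ref = sm.GLM(d["outcome"], X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(pf.fit.params.to_numpy(), ref.params.to_numpy(), atol=1e-6)

    def test_covariates_kept_in_reduced_model(self, null_data):
        data = null_data.copy()
        rng = np.random.default_rng(3)
        data["age"] = rng.normal(50, 8, len(data))
        pf = fit_pattern(data, parse_label("Int_AE_oo"), "snp1", "env_g3", "outcome",
                         covariates=["age"])
        assert pf.estimable
        assert "age" in pf.fit.term_names

    def test_missing_column_raises(self, null_data):
        with pytest.raises(KeyError, match="not_there"):
            fit_pattern(null_data, parse_label("Int_AE_oo"), "not_there", "env_g3", "outcome")


class TestBicProperties:
    def test_identical_column_spans_identical_bic(self, null_data):
        """Affine recoding leaves the span, hence logLik and BIC, unchanged."""
        y = null_data["outcome"].to_numpy(dtype=float)
        s = null_data["snp1"].to_numpy(dtype=float)
        d2 = (null_data["env_g3"] == 2).to_numpy(float)
        d3 = (null_data["env_g3"] == 3).to_numpy(float)
        X1 = pd.DataFrame({"const": 1.0, "S": s, "I2": d2, "I3": d3})
        X2 = pd.DataFrame({"const": 1.0, "S": 2 - s, "I2": d2 + d3, "I3": d3})
        f1, f2 = fit_glm(X1, y, "logistic"), fit_glm(X2, y, "logistic")
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, abs=1e-6)
        assert bic(f1) == pytest.approx(bic(f2), abs=1e-6)

    def test_mint_snp_lrt_invariant_to_env_direction(self, null_data):
        """With the SNP main effect present, S*I(E=1) = S - S*I(E=2) - S*I(E=3):
        reversing the environment direction spans the same space, so the LRT
        statistic is unchanged.  This is why only _oo/_ro patterns exist for
        the SNP-main-plus-interaction structure."""
        d = null_data
        y = d["outcome"].to_numpy(dtype=float)
        s = d["snp1"].to_numpy(dtype=float)
        ind = {lvl: (d["env_g3"] == lvl).to_numpy(float) for lvl in (1, 2, 3)}
        reduced = fit_glm(pd.DataFrame({"const": 1.0, "SNP": s}), y, "logistic")
        stats = []
        for dummies in ([ind[2], ind[3]], [ind[1], ind[2]]):  # ref lowest / highest
            X = pd.DataFrame({"const": 1.0, "SNP": s,
                              "SNP:d1": s * dummies[0], "SNP:d2": s * dummies[1]})
            full = fit_glm(X, y, "logistic")
            stats.append(interaction_test(full, reduced, "lrt")[0])
        assert stats[0] == pytest.approx(stats[1], abs=1e-6)
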
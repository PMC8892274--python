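import math
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import integrate

from alerthabit.features import assemble_analysis_table
from alerthabit.regression import (
    ConditionalLogisticRegression,
    EstimationError,
    ModelSpec,
    RandomInterceptLogisticRegression,
    WithinGroupOLS,
    build_design,
    fit_by_rank,
    fit_fe_logit,
    fit_processing_time,
    fit_re_logit,
    icc_logistic,
    standardized_odds_effect,
    _gh_group_loglike,
)
from alerthabit.simulate import SimulationConfig, simulate_log

RECOVERY_COVARIATES = ["ward_round", "patient_age", "length_of_stay"]


@pytest.fixture(scope="module")
def recovery_table():
    """Default-size simulated dataset (the spec of the generative model
    places beta_H at 1.0) for recovery checks."""
    log, truth = simulate_log(SimulationConfig(seed=42))
    return assemble_analysis_table(log), truth


class TestIccLogistic:
    @pytest.mark.parametrize("sigma_u2,expected", [
        (0.0, 0.0),
        (math.pi**2 / 3, 0.5),
        (3 * math.pi**2 / 3, 0.75),
    ])
    def test_formula(self, sigma_u2, expected):
        assert icc_logistic(sigma_u2) == pytest.approx(expected, abs=1e-12)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_logistic(-0.1)


class TestStandardizedEffect:
    def test_zero_coefficient(self, recovery_table):
        table, _ = recovery_table
        res = fit_fe_logit(table, ModelSpec(covariates=RECOVERY_COVARIATES))
        res.terms.loc["H_0.05", "coef"] = 0.0
        eff = standardized_odds_effect(res, "H_0.05", sd=0.3)
        assert eff["per_sd_odds_ratio"] == pytest.approx(1.0)
        assert eff["odds_increase_times"] == pytest.approx(0.0)

    def test_log2_algebra(self, recovery_table):
        table, _ = recovery_table
        res = fit_fe_logit(table, ModelSpec(covariates=RECOVERY_COVARIATES))
        res.terms.loc["H_0.05", "coef"] = math.log(2) / 0.25
        eff = standardized_odds_effect(res, "H_0.05", sd=0.25)
        assert eff["odds_increase_times"] == pytest.approx(1.0)

    def test_nonpositive_sd_rejected(self, recovery_table):
        table, _ = recovery_table
        res = fit_fe_logit(table, ModelSpec(covariates=RECOVERY_COVARIATES))
        with pytest.raises(ValueError):
            standardized_odds_effect(res, "H_0.05", sd=0.0)


class TestConditionalLogit:
    def test_matches_statsmodels_oracle(self, recovery_table):
        """Independent check against statsmodels' conditional ML on a
        30-physician subset."""
        from statsmodels.discrete.conditional_models import ConditionalLogit
        table, _ = recovery_table
        sub = table[table.physician_id.isin(table.physician_id.unique()[:30])]
        X = build_design(sub, "H_0.05", ["ward_round", "patient_age"])
        y = sub["dismiss"].to_numpy(float)
        mine = ConditionalLogisticRegression().fit(X, y, sub["physician_id"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = ConditionalLogit(
                y, X.to_numpy(), groups=pd.factorize(sub["physician_id"])[0]
            ).fit(disp=False)
        np.testing.assert_allclose(mine.coef_, ref.params, atol=2e-4)
        np.testing.assert_allclose(mine.bse_, ref.bse, rtol=1e-2)

    def test_seed42_recovery_within_quarter(self, recovery_table):
        table, truth = recovery_table
        res = fit_fe_logit(table, ModelSpec(covariates=RECOVERY_COVARIATES))
        beta = res.terms.loc["H_0.05", "coef"]
        assert abs(beta - truth.config.beta_H) < 0.25
        assert res.converged

    def test_odds_ratio_identity(self, recovery_table):
        table, _ = recovery_table
        res = fit_fe_logit(table, ModelSpec(covariates=RECOVERY_COVARIATES))
        np.testing.assert_allclose(
            res.terms["odds_ratio"], np.exp(res.terms["coef"]), atol=1e-12)
        assert (res.terms["ci_low"] <= res.terms["coef"]).all()
        assert (res.terms["coef"] <= res.terms["ci_high"]).all()

    def test_group_constant_covariate_is_inert(self, recovery_table):
        """A physician-constant covariate cancels from the conditional
        likelihood; the habit coefficient must not move."""
        table, _ = recovery_table
        base = fit_fe_logit(table, ModelSpec(covariates=RECOVERY_COVARIATES))
        aug = fit_fe_logit(table, ModelSpec(
            covariates=RECOVERY_COVARIATES + ["physician_rank"]))
        assert abs(base.terms.loc["H_0.05", "coef"]
                   - aug.terms.loc["H_0.05", "coef"]) < 1e-6
        assert any(t.startswith("physician_rank") for t in aug.dropped_terms)

    def test_all_dismiss_group_contributes_nothing(self, recovery_table):
        """Dropping physicians without outcome variation leaves the
        estimates unchanged (they carry no conditional information)."""
        table, _ = recovery_table
        per = table.groupby("physician_id")["dismiss"].agg(["mean"])
        varying = per.index[(per["mean"] > 0) & (per["mean"] < 1)]
        full = fit_fe_logit(table, ModelSpec(covariates=RECOVERY_COVARIATES))
        pruned = fit_fe_logit(table[table.physician_id.isin(varying)],
                              ModelSpec(covariates=RECOVERY_COVARIATES))
        assert full.n_groups_dropped > 0 and pruned.n_groups_dropped == 0
        np.testing.assert_allclose(
            full.terms["coef"], pruned.terms["coef"], atol=1e-8)

    def test_no_varying_group_raises(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(EstimationError):
            ConditionalLogisticRegression().fit(
                df, [1, 1, 0, 0], ["g1", "g1", "g2", "g2"])


class TestRandomInterceptLogit:
    def test_marginal_likelihood_matches_adaptive_quadrature(self):
        """Oracle: scipy adaptive quadrature of the per-group integral."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 2))
        beta = np.array([0.4, -0.7])
        y = rng.integers(0, 2, 12).astype(float)
        codes = np.repeat([0, 1, 2], 4)
        log_sigma = math.log(0.8)
        nodes, weights = np.polynomial.hermite.hermgauss(40)
        gh = _gh_group_loglike(X @ beta, y, codes, 3, log_sigma, nodes, weights)
        sigma = 0.8
        for g in range(3):
            idx = codes == g
            eta0 = (X @ beta)[idx]
            yg = y[idx]

            def integrand(u):
                p = 1 / (1 + np.exp(-(eta0 + u)))
                lik = np.prod(p**yg * (1 - p) ** (1 - yg))
                return lik * np.exp(-u**2 / (2 * sigma**2)) / (
                    sigma * math.sqrt(2 * math.pi))

            ref, _ = integrate.quad(integrand, -8 * sigma, 8 * sigma)
            assert gh[g] == pytest.approx(math.log(ref), abs=1e-8)

    def test_sigma_zero_generator_gives_near_zero_icc(self):
        log, _ = simulate_log(SimulationConfig(
            n_physicians=80, n_patients=160, sigma_u=0.0, seed=3))
        table = assemble_analysis_table(log)
        res = fit_re_logit(table, ModelSpec(
            covariates=RECOVERY_COVARIATES, estimator="random_effects"))
        assert res.icc < 0.05

    def test_agrees_with_fe_signs(self, recovery_table):
        table, _ = recovery_table
        sub = table[table.physician_id.isin(table.physician_id.unique()[:60])]
        fe = fit_fe_logit(sub, ModelSpec(covariates=RECOVERY_COVARIATES))
        re = fit_re_logit(sub, ModelSpec(covariates=RECOVERY_COVARIATES,
                                         estimator="random_effects"))
        for term in ["H_0.05", "ward_round"]:
            assert np.sign(fe.terms.loc[term, "coef"]) == \
                np.sign(re.terms.loc[term, "coef"])
        assert 0 <= re.icc < 1


class TestWithinGroupOLS:
    def test_matches_dummy_variable_ols(self):
        """Oracle: OLS with explicit group dummies gives identical slopes
        and standard errors."""
        rng = np.random.default_rng(8)
        G, T = 12, 15
        groups = np.repeat(np.arange(G), T)
        x = rng.normal(size=G * T)
        alpha_g = rng.normal(size=G)
        y = 2.0 * x + alpha_g[groups] + rng.normal(size=G * T)
        est = WithinGroupOLS().fit(pd.DataFrame({"x": x}), y, groups)
        dummies = pd.get_dummies(groups).to_numpy(dtype=float)
        ref = sm.OLS(y, np.column_stack([x, dummies])).fit()
        assert est.coef_[0] == pytest.approx(ref.params[0], abs=1e-10)
        assert est.bse_[0] == pytest.approx(ref.bse[0], abs=1e-10)


class TestProcessingTimeModels:
    def test_negative_habit_coefficient_recovered(self, recovery_table):
        table, _ = recovery_table
        res = fit_processing_time(table, estimator="fixed_effects",
                                  covariates=RECOVERY_COVARIATES)
        h = res.terms.loc["H_0.05"]
        assert h["coef"] < 0 and h["ci_high"] < 0

    def test_null_latency_generator_covers_zero(self):
        """theta1 = 0: the habit coefficient's 95% CI covers 0 in at
        least 90% of replicates."""
        covered = 0
        n_rep = 100
        for seed in range(1, n_rep + 1):
            log, _ = simulate_log(SimulationConfig(
                n_physicians=30, n_patients=60, theta1=0.0, seed=seed))
            table = assemble_analysis_table(log)
            res = fit_processing_time(table, estimator="fixed_effects",
                                      covariates=RECOVERY_COVARIATES)
            h = res.terms.loc["H_0.05"]
            covered += h["ci_low"] <= 0 <= h["ci_high"]
        assert covered >= 90

    def test_pooled_and_fe_differ_under_confounding(self):
        """Physician intercepts correlated with habit levels: pooled OLS
        absorbs the between-physician confounding, the within estimator
        does not."""
        rng = np.random.default_rng(4)
        G, T = 30, 40
        groups = np.repeat(np.arange(G), T)
        mu_g = np.linspace(0, 1, G)           # physician habit level
        H = np.clip(mu_g[groups] + rng.normal(0, 0.1, G * T), 0, 1)
        intercept_g = 5.0 * mu_g              # confounded intercepts
        y = intercept_g[groups] - 1.0 * H + rng.normal(0, 0.5, G * T)
        X = pd.DataFrame({"H_0.05": H})
        fe = WithinGroupOLS().fit(X, y, groups)
        pooled = sm.OLS(y, sm.add_constant(H)).fit()
        assert fe.coef_[0] == pytest.approx(-1.0, abs=0.15)
        assert pooled.params[1] > fe.coef_[0] + 1.0   # badly confounded upward

    def test_random_effects_estimator_runs(self, recovery_table):
        table, _ = recovery_table
        sub = table[table.physician_id.isin(table.physician_id.unique()[:50])]
        res = fit_processing_time(sub, estimator="random_effects",
                                  covariates=RECOVERY_COVARIATES)
        assert res.sigma_u2 is not None and res.icc is not None
        assert res.terms.loc["H_0.05", "coef"] < 0


class TestFitByRank:
    def test_positive_habit_effect_across_all_ranks(self):
        log, _ = simulate_log(SimulationConfig(
            n_physicians=120, n_patients=240, beta_H=1.5, seed=11))
        table = assemble_analysis_table(log)
        results = fit_by_rank(table, ModelSpec(covariates=RECOVERY_COVARIATES))
        fitted = {r: m for r, m in results.items() if m.converged}
        assert len(fitted) == 4
        for rank, res in fitted.items():
            assert res.terms.loc["H_0.05", "coef"] > 0, rank

    def test_subsample_rows_partition_the_table(self, recovery_table):
        table, _ = recovery_table
        results = fit_by_rank(table, ModelSpec(covariates=RECOVERY_COVARIATES))
        rows_by_rank = table["physician_rank"].value_counts()
        for rank, res in results.items():
            if res.converged:
                assert res.nobs <= rows_by_rank.get(rank, 0)
        assert int(rows_by_rank.sum()) == len(table)

    def test_missing_stratum_reported_not_raised(self, recovery_table):
        table, _ = recovery_table
        sub = table[table["physician_rank"] != "fellow"]
        results = fit_by_rank(sub, ModelSpec(covariates=RECOVERY_COVARIATES))
        assert results["fellow"].converged is False
        assert "empty" in results["fellow"].message

    def test_degenerate_stratum_graceful(self):
        """A stratum with one all-dismissing physician yields a failure
        record, not an exception."""
        log, _ = simulate_log(SimulationConfig(
            n_physicians=8, n_patients=16, seed=2))
        table = assemble_analysis_table(log)
        one_phys = table[table.physician_id == table.physician_id.iloc[0]].copy()
        one_phys["dismiss"] = 1
        one_phys["physician_rank"] = "fellow"
        rest = table[table.physician_id != table.physician_id.iloc[0]].copy()
        rest["physician_rank"] = "resident"
        combined = pd.concat([one_phys, rest], ignore_index=True)
        results = fit_by_rank(combined, ModelSpec(covariates=RECOVERY_COVARIATES))
        assert results["fellow"].converged is False
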
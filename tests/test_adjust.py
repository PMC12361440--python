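"""Tests of GLM family selection, fitting, BH calling, adjustment and VIF."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from interomics import (
    adjust_layers,
    adjust_values,
    call_ga_regulated,
    design_matrix,
    fit_glm,
    generate_cohort,
    screen_covariates,
    select_family,
)
from interomics.adjust import GlmFit, TERMS, _ols_batch, fit_layer

from conftest import make_layer


def cohort_one_sex(n=160, seed=0, sex="female"):
    cohort = generate_cohort({"Control": n // 3, "PE": n // 3, "PTD": n - 2 * (n // 3)}, seed=seed)
    cohort["fetal_sex"] = sex
    return cohort


class TestSelectFamily:
    def test_normal_draws_mostly_gaussian(self):
        """Seeded standard-normal vectors pass the AD test ~95% of the time."""
        gaussian = 0
        for seed in range(100):
            v = np.random.default_rng(seed).standard_normal(300)
            gaussian += select_family(v).decision == "gaussian"
        assert gaussian >= 87  # nominal 95 with binomial noise

    def test_lognormal_draws_are_gamma(self):
        for seed in range(20):
            v = np.random.default_rng(seed).lognormal(0, 1, size=300)
            decision = select_family(v)
            assert decision.decision == "gamma"
            assert decision.ad_p < 0.05

    def test_outlier_fraction_rule(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.uniform(-1, 1, 96), [40, -40, 40, -40]])
        decision = select_family(v)
        assert decision.outlier_frac == pytest.approx(0.04)
        assert decision.decision == "gamma"

    def test_pure_function_of_vector(self):
        v = np.random.default_rng(3).standard_normal(50)
        a, b = select_family(v), select_family(v)
        assert (a.ad_p, a.outlier_frac, a.decision) == (b.ad_p, b.outlier_frac, b.decision)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            select_family(np.ones(20))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            select_family(np.arange(5.0))


class TestFitGlm:
    def test_noiseless_gaussian_recovery(self):
        cohort = cohort_one_sex()
        X = design_matrix(cohort)
        y = 2.0 + 0.5 * X["ga"]
        decision = select_family(np.random.default_rng(0).standard_normal(len(y)))
        decision.decision = "gaussian"
        fit = fit_glm(y, X, decision)
        assert fit.coef["ga"] == pytest.approx(0.5, abs=1e-9)
        assert fit.coef["intercept"] == pytest.approx(2.0, abs=1e-7)
        assert fit.ga_p < 1e-12

    def test_noiseless_gamma_log_recovery(self):
        cohort = cohort_one_sex()
        X = design_matrix(cohort)
        y = np.exp(1.0 + 0.2 * X["ga"])
        decision = select_family(np.random.default_rng(0).lognormal(0, 1, len(y)))
        fit = fit_glm(y, X, decision)
        assert fit.family == "gamma" and fit.link == "log"
        assert fit.converged
        assert fit.coef["ga"] == pytest.approx(0.2, abs=1e-6)

    def test_gamma_shift_for_nonpositive_values(self):
        cohort = cohort_one_sex(n=60)
        X = design_matrix(cohort)
        rng = np.random.default_rng(2)
        y = rng.normal(0.0, 1.0, len(X))  # includes negatives
        decision = select_family(rng.lognormal(0, 1, len(X)))
        fit = fit_glm(y, X, decision)
        assert fit.shift > 0
        assert fit.converged

    def test_slope_recovery_within_two_se(self):
        """Monte-Carlo: mean slope estimate over 200 replicates near 0.5."""
        cohort = cohort_one_sex(n=160, seed=5)
        X = design_matrix(cohort)[list(TERMS)].to_numpy()
        rng = np.random.default_rng(99)
        estimates = []
        for _ in range(200):
            y = 2.0 + 0.5 * X[:, TERMS.index("ga")] + rng.normal(0, 1, len(X))
            beta, _ = _ols_batch(y, X)
            estimates.append(beta[TERMS.index("ga"), 0])
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(xtx_inv[TERMS.index("ga"), TERMS.index("ga")])  # sigma = 1
        assert abs(np.mean(estimates) - 0.5) < 2 * se


class TestCallGaRegulated:
    def _fits(self, pvals):
        return [
            GlmFit(f"a{i}", "metabolites", "female", "gaussian", "identity",
                   {t: 0.0 for t in TERMS}, p)
            for i, p in enumerate(pvals)
        ]

    def test_single_analyte_bh_identity(self):
        fits = self._fits([0.01])
        called = call_ga_regulated(fits)
        assert called == {"a0"}
        assert fits[0].ga_q == pytest.approx(0.01)

    def test_null_false_call_rate(self):
        rng = np.random.default_rng(0)
        called = call_ga_regulated(self._fits(rng.uniform(size=1000)))
        assert len(called) <= 0.05 * 1000

    def test_power_on_planted_signals(self):
        """50 signals at 5 SE among 1000: nearly all recovered (MC, 3 reps)."""
        recovered = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            z = rng.standard_normal(1000)
            z[:50] += 5.0  # planted at 5 standard errors
            p = 2 * stats.norm.sf(np.abs(z))
            called = call_ga_regulated(self._fits(p))
            recovered.append(len({f"a{i}" for i in range(50)} & called))
        assert np.mean(recovered) >= 45

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            call_ga_regulated([])


class TestAdjustValues:
    def test_noiseless_fit_adjusts_to_constant(self):
        cohort = cohort_one_sex(n=60)
        X = design_matrix(cohort)
        y = 2.0 + 0.5 * X["ga"] + 0.01 * X["bmi_sq"]
        decision = select_family(np.random.default_rng(0).standard_normal(len(y)))
        decision.decision = "gaussian"
        fit = fit_glm(y, X, decision)
        adj_int = adjust_values(y, fit, X, preserve="intercept")
        assert np.allclose(adj_int, fit.coef["intercept"], atol=1e-8)
        adj_mean = adjust_values(y, fit, X, preserve="mean")
        assert np.allclose(adj_mean, y.mean(), atol=1e-8)

    def test_zero_coefficient_fit_is_identity(self):
        cohort = cohort_one_sex(n=40)
        X = design_matrix(cohort)
        rng = np.random.default_rng(1)
        y = rng.normal(size=len(X))
        fit = GlmFit("a", "m", "female", "gaussian", "identity",
                     {t: 0.0 for t in TERMS}, 0.5)
        assert np.allclose(adjust_values(y, fit, X), y)

    def test_adjusted_values_refit_to_zero_ga_slope(self):
        cohort = cohort_one_sex(n=100)
        X = design_matrix(cohort)
        y = 1.0 + 0.5 * X["ga"]
        decision = select_family(np.random.default_rng(0).standard_normal(len(y)))
        decision.decision = "gaussian"
        fit = fit_glm(y, X, decision)
        for preserve in ("mean", "intercept"):
            adj = adjust_values(y, fit, X, preserve=preserve)
            refit = fit_glm(adj, X, decision)
            assert abs(refit.coef["ga"]) < 1e-8

    def test_remove_can_be_restricted_to_ga(self):
        cohort = cohort_one_sex(n=60)
        X = design_matrix(cohort)
        y = 2.0 + 0.5 * X["ga"] + 0.3 * X["labor"]
        decision = select_family(np.random.default_rng(0).standard_normal(len(y)))
        decision.decision = "gaussian"
        fit = fit_glm(y, X, decision)
        adj = adjust_values(y, fit, X, remove=("ga",), preserve="intercept")
        # labor effect survives, GA effect does not
        assert np.ptp(adj[X["labor"] == 1]) < 1e-8
        assert abs(adj[X["labor"] == 1].mean() - adj[X["labor"] == 0].mean()) > 0.2


class TestAdjustLayers:
    def _study(self, seed=0):
        cohort = generate_cohort({"Control": 40, "PE": 40}, seed=seed)
        rng = np.random.default_rng(seed + 1)
        ga = cohort["ga_weeks"].to_numpy()
        female = (cohort["fetal_sex"] == "female").to_numpy()
        vals = rng.normal(10, 0.5, size=(len(cohort), 20))
        vals[female, 0] += 0.8 * (ga[female] - 37)  # female-specific GA analyte
        vals[:, 1] += 0.8 * (ga - 37)  # shared GA analyte
        layer = make_layer(vals, name="metabolites")
        layer.values.index = cohort.index
        return cohort, [layer]

    def test_ga_regulated_sets_respect_sex_structure(self):
        cohort, layers = self._study()
        _, fits, ga_regulated = adjust_layers(layers, cohort)
        assert "metabolites:a000" in ga_regulated["female"]
        assert "metabolites:a000" not in ga_regulated["male"]
        assert "metabolites:a001" in ga_regulated["female"] & ga_regulated["male"]

    def test_sex_stratification_is_strict(self):
        """Perturbing male samples never changes female fits."""
        cohort, layers = self._study()
        _, fits_before, _ = adjust_layers([l.copy() for l in layers], cohort)
        male_ids = cohort.index[cohort["fetal_sex"] == "male"]
        layers[0].values.loc[male_ids] += 5.0
        _, fits_after, _ = adjust_layers(layers, cohort)
        f_before = fits_before[fits_before["sex"] == "female"].reset_index(drop=True)
        f_after = fits_after[fits_after["sex"] == "female"].reset_index(drop=True)
        pd.testing.assert_frame_equal(f_before, f_after)

    def test_adjusted_ga_analyte_loses_ga_dependence(self):
        cohort, layers = self._study()
        adjusted, _, _ = adjust_layers(layers, cohort)
        female = cohort.index[cohort["fetal_sex"] == "female"]
        y = adjusted[0].values.loc[female, "a000"]
        ga = cohort.loc[female, "ga_weeks"]
        slope = np.polyfit(ga, y, 1)[0]
        assert abs(slope) < 0.1  # 0.8 before adjustment


class TestScreenCovariates:
    def test_independent_covariates_have_unit_vif(self):
        rng = np.random.default_rng(0)
        n = 5000
        cohort = pd.DataFrame(
            dict(
                condition="Control", fetal_sex="female",
                ga_weeks=rng.uniform(37, 42, n),
                bmi=rng.uniform(18, 40, n),
                labor_init=rng.integers(0, 2, n),
                smoking=rng.integers(0, 2, n),
                drug_use=rng.integers(0, 2, n),
            ),
            index=[f"S{i}" for i in range(n)],
        )
        _, vif = screen_covariates(cohort)
        assert (np.abs(vif["vif"] - 1.0) < 0.2).all()

    def test_duplicated_covariate_flagged_infinite(self):
        rng = np.random.default_rng(1)
        n = 50
        smoke = rng.integers(0, 2, n)
        cohort = pd.DataFrame(
            dict(condition="Control", fetal_sex="male",
                 ga_weeks=rng.uniform(37, 42, n), bmi=rng.uniform(18, 40, n),
                 labor_init=rng.integers(0, 2, n), smoking=smoke, drug_use=smoke),
            index=[f"S{i}" for i in range(n)],
        )
        _, vif = screen_covariates(cohort)
        assert np.isinf(vif.loc["smoking", "vif"])
        assert vif.loc["smoking", "flag"]

    def test_constant_covariate_undefined_vif(self):
        rng = np.random.default_rng(2)
        n = 40
        cohort = pd.DataFrame(
            dict(condition="Control", fetal_sex="male",
                 ga_weeks=rng.uniform(37, 42, n), bmi=rng.uniform(18, 40, n),
                 labor_init=rng.integers(0, 2, n), smoking=0,
                 drug_use=rng.integers(0, 2, n)),
            index=[f"S{i}" for i in range(n)],
        )
        _, vif = screen_covariates(cohort)
        assert np.isnan(vif.loc["smoking", "vif"])
        assert vif.loc["smoking", "flag"]

    def test_bivariate_closed_form(self):
        """Two covariates at correlation r: VIF ~ 1/(1 - r^2)."""
        rng = np.random.default_rng(3)
        n = 4000
        r = 0.8
        ga = rng.normal(39, 1.0, n)
        bmi_sq_target = r * (ga - 39) / 1.0 + np.sqrt(1 - r**2) * rng.standard_normal(n)
        bmi = np.sqrt(np.abs(bmi_sq_target * 40 + 700))
        cohort = pd.DataFrame(
            dict(condition="Control", fetal_sex="male", ga_weeks=np.clip(ga, 37, 42),
                 bmi=bmi, labor_init=rng.integers(0, 2, n),
                 smoking=rng.integers(0, 2, n), drug_use=rng.integers(0, 2, n)),
            index=[f"S{i}" for i in range(n)],
        )
        X = design_matrix(cohort)
        r_emp = np.corrcoef(X["ga"], X["bmi_sq"])[0, 1]
        _, vif = screen_covariates(cohort)
        assert vif.loc["ga", "vif"] == pytest.approx(1.0 / (1.0 - r_emp**2), rel=0.05)
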
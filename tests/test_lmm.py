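"""Mixed models with CAR(1) residuals, fit indices, and the power simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from esmdyn.data import EsmTable
from esmdyn.lmm import (
    LmmSpec,
    MixedCAR1Model,
    MixedCAR1Results,
    contemporaneous_spec,
    fit_lmm,
    icc,
    lagged_spec,
    power_simulation,
    r2_nakagawa,
    standardize_coefficients,
    validate_social_presence,
    vif_report,
)


def _ri_data(rng, J=20, n=8, beta=(1.0, 0.5), tau=1.0, sigma=1.0, rho=0.0):
    """Random-intercept (optionally CAR(1)) data with known truth."""
    ys, xs, gs, ts = [], [], [], []
    for j in range(J):
        t = np.sort(rng.uniform(0, 10, n))
        x = rng.standard_normal(n)
        if rho > 0:
            C = rho ** np.abs(t[:, None] - t[None, :])
            e = np.linalg.cholesky(sigma ** 2 * C) @ rng.standard_normal(n)
        else:
            e = rng.normal(0, sigma, n)
        ys.append(beta[0] + beta[1] * x + rng.normal(0, tau) + e)
        xs.append(x)
        gs.append(np.full(n, j))
        ts.append(t)
    y = np.concatenate(ys)
    x = np.concatenate(xs)
    X = np.column_stack([np.ones_like(x), x])
    return y, X, np.concatenate(gs), np.concatenate(ts)


class TestLikelihood:
    def test_matches_joint_mvn_oracle_no_car(self):
        """Profile-free loglik equals the directly assembled joint density."""
        rng = np.random.default_rng(0)
        y, X, g, t = _ri_data(rng, J=3, n=4)
        m = MixedCAR1Model(y, X, ["c", "x"], g, t, random_slope=False,
                           car1=False, method="ML")
        beta = np.array([0.8, 0.4])
        tau2, sig2 = 0.9, 1.3
        ll = m.marginal_loglik(beta, np.array([[tau2]]), np.sqrt(sig2), 0.0)
        oracle = 0.0
        for j in range(3):
            sel = g == j
            V = tau2 * np.ones((4, 4)) + sig2 * np.eye(4)
            oracle += stats.multivariate_normal(
                (X[sel] @ beta), V).logpdf(y[sel])
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_matches_joint_mvn_oracle_with_car_and_slope(self):
        rng = np.random.default_rng(1)
        y, X, g, t = _ri_data(rng, J=4, n=5)
        m = MixedCAR1Model(y, X, ["c", "x"], g, t, random_slope=True,
                           car1=True, method="ML")
        beta = np.array([0.2, -0.3])
        psi = np.array([[0.8, 0.1], [0.1, 0.05]])
        sigma, rho = 1.1, 0.4
        ll = m.marginal_loglik(beta, psi, sigma, rho)
        oracle = 0.0
        for j in range(4):
            sel = g == j
            tj = t[sel]
            Z = np.column_stack([np.ones(5), tj])
            C = rho ** np.abs(tj[:, None] - tj[None, :])
            V = Z @ psi @ Z.T + sigma ** 2 * C
            oracle += stats.multivariate_normal(X[sel] @ beta, V).logpdf(y[sel])
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(2)
        y, X, g, t = _ri_data(rng)
        X2 = np.column_stack([X, X[:, 1]])   # exact copy of a predictor
        with pytest.raises(ValueError, match="collinear"):
            MixedCAR1Model(y, X2, ["c", "x", "x_copy"], g, t)

    def test_known_truth_recovery_with_car(self):
        rng = np.random.default_rng(3)
        y, X, g, t = _ri_data(rng, J=50, n=25, beta=(1.0, 0.3), tau=1.0,
                              sigma=1.0, rho=0.5)
        m = MixedCAR1Model(y, X, ["c", "x"], g, t, within_flags=[False, True],
                           random_slope=False, car1=True)
        res = m.fit()
        assert res.params[1] == pytest.approx(0.3, abs=0.05)
        assert res.rho == pytest.approx(0.5, abs=0.1)
        assert res.sigma == pytest.approx(1.0, abs=0.1)
        assert res.sd_intercept == pytest.approx(1.0, abs=0.25)

    def test_agrees_with_statsmodels_mixedlm(self):
        """Random-intercept special case cross-checked against MixedLM."""
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        y, X, g, t = _ri_data(rng, J=25, n=10, beta=(0.5, 0.4), tau=0.8)
        res = MixedCAR1Model(y, X, ["c", "x"], g, t, random_slope=False,
                             car1=False, method="REML").fit()
        smres = sm.MixedLM(y, X, groups=g).fit(reml=True)
        assert res.params == pytest.approx(smres.params[:2], abs=1e-4)
        assert res.bse == pytest.approx(smres.bse[:2], abs=1e-3)
        assert res.sigma ** 2 == pytest.approx(smres.scale, rel=1e-3)


class TestFitIndices:
    def _manual_results(self, var_f, psi, sigma):
        """Assemble a results object with a controlled fixed-effect variance."""
        rng = np.random.default_rng(5)
        n, J = 200, 10
        x = rng.standard_normal(n) * np.sqrt(var_f)
        X = np.column_stack([np.ones(n), x])
        g = np.repeat(np.arange(J), n // J)
        t = np.tile(np.linspace(0, 5, n // J), J)
        m = MixedCAR1Model(rng.standard_normal(n), X, ["c", "x"], g, t,
                           random_slope=psi.shape[0] > 1, car1=False)
        return MixedCAR1Results(model=m, params=np.array([0.0, 1.0]),
                                cov_params=np.eye(2), psi=psi, sigma=sigma,
                                rho=0.0, loglik=0.0, theta=np.zeros(2),
                                converged=True)

    def test_r2_arithmetic(self):
        # var_f = 1, var_r = 1, var_e = 2 -> (0.25, 0.50)
        res = self._manual_results(1.0, np.array([[1.0]]), np.sqrt(2.0))
        r2m, r2c = r2_nakagawa(res)
        assert r2m == pytest.approx(0.25, abs=0.02)
        assert r2c == pytest.approx(0.50, abs=0.02)

    def test_no_random_variance_equalizes_r2(self):
        res = self._manual_results(1.0, np.array([[0.0]]), 1.0)
        r2m, r2c = r2_nakagawa(res)
        assert r2m == pytest.approx(r2c, abs=1e-12)

    def test_intercept_only_marginal_zero(self):
        # slope coefficient zeroed: the fixed predictor explains nothing
        res = self._manual_results(1.0, np.array([[1.0]]), 1.0)
        res.params = np.array([2.0, 0.0])
        r2m, _ = r2_nakagawa(res)
        assert r2m == pytest.approx(0.0, abs=1e-10)

    def test_icc_special_cases(self):
        res = self._manual_results(1.0, np.array([[1.0]]), 1.0)
        assert icc(res) == pytest.approx(0.5)
        res0 = self._manual_results(1.0, np.array([[0.0]]), 1.0)
        assert icc(res0) == 0.0

    def test_icc_recovered_from_icc_half_generator(self):
        rng = np.random.default_rng(6)
        y, X, g, t = _ri_data(rng, J=60, n=20, tau=1.0, sigma=1.0)
        res = MixedCAR1Model(y, X, ["c", "x"], g, t, random_slope=False,
                             car1=False).fit()
        assert icc(res) == pytest.approx(0.5, abs=0.05)


class TestStandardize:
    def test_prestandardized_identity(self):
        rng = np.random.default_rng(7)
        y, X, g, t = _ri_data(rng, J=30, n=10)
        y = (y - y.mean()) / y.std(ddof=1)
        X[:, 1] = (X[:, 1] - X[:, 1].mean()) / X[:, 1].std(ddof=1)
        res = MixedCAR1Model(y, X, ["c", "x"], g, t, random_slope=False,
                             car1=False).fit()
        assert standardize_coefficients(res)["x"] == \
            pytest.approx(res.params[1], abs=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        y, X, g, t = _ri_data(rng, J=20, n=8)
        res1 = MixedCAR1Model(y, X, ["c", "x"], g, t, random_slope=False,
                              car1=False).fit()
        res2 = MixedCAR1Model(2 * y, X, ["c", "x"], g, t, random_slope=False,
                              car1=False).fit()
        assert res2.params[1] == pytest.approx(2 * res1.params[1], abs=1e-4)
        assert standardize_coefficients(res2)["x"] == \
            pytest.approx(standardize_coefficients(res1)["x"], abs=1e-6)


class TestVif:
    def test_orthogonal_predictors_near_one(self):
        rng = np.random.default_rng(9)
        n = 4000
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        y = rng.standard_normal(n)
        g = np.repeat(np.arange(20), n // 20)
        t = np.tile(np.linspace(0, 5, n // 20), 20)
        m = MixedCAR1Model(y, X, ["c", "a", "b", "d"], g, t,
                           random_slope=False, car1=False)
        res = m.fit()
        assert np.allclose(vif_report(res), 1.0, atol=0.1)

    def test_matches_auxiliary_regression_oracle(self):
        rng = np.random.default_rng(10)
        n = 500
        z = rng.standard_normal(n)
        X = np.column_stack([np.ones(n),
                             z + 0.3 * rng.standard_normal(n),
                             z + 0.3 * rng.standard_normal(n),
                             rng.standard_normal(n)])
        g = np.repeat(np.arange(10), 50)
        t = np.tile(np.linspace(0, 5, 50), 10)
        m = MixedCAR1Model(rng.standard_normal(n), X, ["c", "x1", "x2", "x3"],
                           g, t, random_slope=False, car1=False)
        res = m.fit()
        vif = vif_report(res)
        for k in range(1, 4):
            others = [c for c in range(1, 4) if c != k]
            Z = np.column_stack([np.ones(n), X[:, others]])
            bh, *_ = np.linalg.lstsq(Z, X[:, k], rcond=None)
            r2 = 1 - np.sum((X[:, k] - Z @ bh) ** 2) / \
                np.sum((X[:, k] - X[:, k].mean()) ** 2)
            assert vif.iloc[k - 1] == pytest.approx(1 / (1 - r2), rel=0.02)


class TestEsmModels:
    def test_contemporaneous_and_lagged_fit(self, small_esm):
        res = fit_lmm(small_esm, contemporaneous_spec())
        tab = res.summary()
        assert tab.attrs["r2_marginal"] <= tab.attrs["r2_conditional"] <= 1
        assert 0 <= tab.attrs["icc"] <= 1
        assert 0 <= res.rho < 1
        lag = fit_lmm(small_esm, lagged_spec())
        assert lag.model.n_obs == res.model.n_obs - small_esm.n_subjects

    def test_validation_model_recovers_positive_coupling(self, small_esm):
        res = validate_social_presence(small_esm)
        beta = res.standardized()["log_bt"]
        lo, hi = res.conf_int()[1]
        assert beta > 0.2
        assert lo > 0

    def test_validation_model_null_coupling(self):
        """When people counts ignore Bluetooth, the slope is ~0."""
        from esmdyn.simulate import DesignConfig, OuGeneratorParams, generate_dataset
        p = OuGeneratorParams(people_link=(0.3, 0.0))
        esm, _ = generate_dataset(DesignConfig(n_subjects=25, n_days=7, seed=13),
                                  params=p, seed=13)
        res = validate_social_presence(esm)
        assert abs(res.standardized()["log_bt"]) < 0.08


class TestPower:
    def test_size_under_null(self):
        res = power_simulation(15, 10, 0.0, reps=400, seed=0)
        assert res["power"] == pytest.approx(0.05, abs=0.035)

    def test_against_normal_approximation(self):
        """n=21 x 42, r=0.1: power ~ Phi(0.1 sqrt(882) - 1.96) ~ 0.84."""
        res = power_simulation(21, 42, 0.1, reps=600, seed=1)
        approx = stats.norm.cdf(0.1 * np.sqrt(21 * 42) - 1.96)
        assert res["power"] == pytest.approx(approx, abs=0.05)

    def test_monotone_in_n_and_effect(self):
        lo = power_simulation(10, 20, 0.1, reps=300, seed=2)["power"]
        hi_n = power_simulation(30, 20, 0.1, reps=300, seed=2)["power"]
        hi_r = power_simulation(10, 20, 0.25, reps=300, seed=2)["power"]
        assert hi_n >= lo - 0.03
        assert hi_r >= lo - 0.03

    def test_warns_on_few_reps(self):
        with pytest.warns(UserWarning):
            power_simulation(5, 5, 0.1, reps=50, seed=3)

    def test_fast_fitter_agrees_with_statsmodels(self):
        import statsmodels.api as sm
        from esmdyn.lmm import _fit_ri_ml
        rng = np.random.default_rng(11)
        J, n = 15, 12
        x = rng.standard_normal(J * n)
        y = 0.3 * x + np.repeat(rng.normal(0, 1, J), n) + \
            rng.standard_normal(J * n)
        slope, se, _ = _fit_ri_ml(y, x, n)
        smres = sm.MixedLM(y, np.column_stack([np.ones_like(x), x]),
                           groups=np.repeat(np.arange(J), n)).fit(reml=False)
        assert slope == pytest.approx(smres.params[1], abs=1e-5)
        assert se == pytest.approx(smres.bse[1], rel=0.02)
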
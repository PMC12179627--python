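"""Within/between mixed-effects models with continuous-time AR(1) residuals.

The working model for an outcome ``y_ij`` (assessment *i* in subject *j*) is

    y_ij = x_ij' beta + z_ij' u_j + e_ij,
    u_j ~ N(0, Psi),   cor(e_ij, e_i'j) = rho^{|t_ij - t_i'j|},

with level-1 predictors centered within subject (cwc), level-2 predictors
being grand-mean-centered subject means (cmc), random intercept and time
slope, and a continuous-time AR(1) residual correlation over the irregular
assessment times (in days).  Estimation maximizes the marginal Gaussian
likelihood (ML or REML) per subject with the fixed effects profiled out.

Also here: Nakagawa marginal/conditional R^2, ICC, VIF, standardized
coefficients, the Bluetooth-validation model, and the simulation-based power
analysis for a within-person effect in a random-intercept model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .data import EsmTable, add_centered, filter_complete, lag_predictors, log1p_transform

__all__ = [
    "LmmSpec",
    "MixedCAR1Model",
    "MixedCAR1Results",
    "fit_lmm",
    "standardize_coefficients",
    "r2_nakagawa",
    "icc",
    "vif_report",
    "validate_social_presence",
    "power_simulation",
    "contemporaneous_spec",
    "lagged_spec",
]

EMOTIONS = ["anger", "dejection", "fatigue", "vigor"]


@dataclass
class LmmSpec:
    """Specification of the within/between mixed model."""

    outcome: str = "log_bt"
    within: list = field(default_factory=lambda: EMOTIONS + ["control"])
    between: list = field(default_factory=lambda: EMOTIONS + ["control"])
    include_time: bool = True
    lagged: bool = False
    random_slope: bool = True
    car1: bool = True
    method: str = "REML"


def contemporaneous_spec(outcome: str = "log_bt") -> LmmSpec:
    return LmmSpec(outcome=outcome)


def lagged_spec(outcome: str = "log_bt") -> LmmSpec:
    return LmmSpec(outcome=outcome, lagged=True)


class ConvergenceWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# core model
# ---------------------------------------------------------------------------

class MixedCAR1Model:
    """Marginal-likelihood mixed model with CAR(1) residual correlation.

    Parameters are the outcome ``y``, fixed design ``X`` with ``names``
    (first column expected to be the intercept), subject labels ``groups``,
    assessment times ``times`` (days), and a boolean ``within`` flag per fixed
    column used only for the degrees-of-freedom convention.
    """

    def __init__(self, y, X, names, groups, times, within_flags=None,
                 random_slope: bool = True, car1: bool = True, method: str = "REML"):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.names = list(names)
        self.times = np.asarray(times, dtype=float)
        self.random_slope = random_slope
        self.car1 = car1
        self.method = method.upper()
        if self.method not in ("ML", "REML"):
            raise ValueError("method must be ML or REML")
        self.within_flags = (np.zeros(len(names), dtype=bool)
                             if within_flags is None else np.asarray(within_flags))
        groups = np.asarray(groups)
        self._check_design()
        # per-subject index slices (data assumed grouped; enforce by argsort)
        order = np.argsort(groups, kind="stable")
        self._order = order
        self.y = self.y[order]
        self.X = self.X[order]
        self.times = self.times[order]
        groups = groups[order]
        _, starts = np.unique(groups, return_index=True)
        starts = np.sort(starts)
        self._slices = [slice(a, b) for a, b in
                        zip(starts, list(starts[1:]) + [len(groups)])]
        self.n_obs = len(self.y)
        self.n_subjects = len(self._slices)
        self.k_fe = self.X.shape[1]
        # cache per-subject random-effect designs and |t_a - t_b| lag matrices
        self._Zs = [self._z(sl) for sl in self._slices]
        self._lags = [np.abs(self.times[sl][:, None] - self.times[sl][None, :])
                      for sl in self._slices]

    def _check_design(self) -> None:
        X = self.X
        if np.linalg.matrix_rank(X) < X.shape[1]:
            # identify offending columns by near-perfect pairwise correlation
            bad = []
            sd = X.std(axis=0)
            for a in range(X.shape[1]):
                for b in range(a + 1, X.shape[1]):
                    if sd[a] > 0 and sd[b] > 0:
                        r = np.corrcoef(X[:, a], X[:, b])[0, 1]
                        if abs(r) > 1 - 1e-10:
                            bad.append((self.names[a], self.names[b]))
            raise ValueError(f"singular fixed-effect design; collinear columns: {bad or 'rank-deficient'}")

    # -- covariance assembly -------------------------------------------

    def _z(self, sl: slice) -> np.ndarray:
        t = self.times[sl]
        if self.random_slope:
            return np.column_stack([np.ones(t.size), t])
        return np.ones((t.size, 1))

    def _resid_corr(self, j: int, rho: float) -> np.ndarray:
        lag = self._lags[j]
        if not self.car1 or rho <= 1e-300:
            return np.eye(lag.shape[0])
        return np.exp(np.log(rho) * lag)

    def marginal_loglik(self, beta, psi, sigma, rho) -> float:
        """Exact ML log-likelihood at the given parameters (no profiling)."""
        psi = np.atleast_2d(psi)
        total = 0.0
        for j, sl in enumerate(self._slices):
            Z = self._Zs[j]
            V = Z @ psi @ Z.T + sigma ** 2 * self._resid_corr(j, rho)
            r = self.y[sl] - self.X[sl] @ beta
            L = np.linalg.cholesky(V)
            a = np.linalg.solve(L, r)
            total += -0.5 * (r.size * np.log(2 * np.pi)
                             + 2 * np.sum(np.log(np.diag(L))) + a @ a)
        return float(total)

    # -- profiled objective --------------------------------------------

    def _unpack_theta(self, theta):
        k = 0
        log_sigma = theta[k]; k += 1
        rho = special.expit(theta[k]) if self.car1 else 0.0
        if self.car1:
            k += 1
        if self.random_slope:
            l11, l21, l22 = np.exp(theta[k]), theta[k + 1], np.exp(theta[k + 2])
            Lc = np.array([[l11, 0.0], [l21, l22]])
        else:
            Lc = np.array([[np.exp(theta[k])]])
        return np.exp(log_sigma), rho, Lc @ Lc.T

    def _profiled(self, theta):
        """(-loglik, beta_hat, cov_beta) with beta profiled by GLS."""
        sigma, rho, psi = self._unpack_theta(theta)
        XtVX = np.zeros((self.k_fe, self.k_fe))
        XtVy = np.zeros(self.k_fe)
        yty = 0.0
        logdet = 0.0
        for j, sl in enumerate(self._slices):
            Z = self._Zs[j]
            V = Z @ psi @ Z.T + sigma ** 2 * self._resid_corr(j, rho)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return 1e10, None, None
            Xs = np.linalg.solve(L, self.X[sl])
            ys = np.linalg.solve(L, self.y[sl])
            XtVX += Xs.T @ Xs
            XtVy += Xs.T @ ys
            yty += ys @ ys
            logdet += 2 * np.sum(np.log(np.diag(L)))
        try:
            cov_beta = np.linalg.inv(XtVX)
        except np.linalg.LinAlgError:
            return 1e10, None, None
        beta = cov_beta @ XtVy
        quad = yty - XtVy @ beta
        ll = -0.5 * (self.n_obs * np.log(2 * np.pi) + logdet + quad)
        if self.method == "REML":
            sign, ld = np.linalg.slogdet(XtVX)
            ll += -0.5 * ld + 0.5 * self.k_fe * np.log(2 * np.pi)
        return -ll, beta, cov_beta

    def _n_theta(self) -> int:
        return 1 + (1 if self.car1 else 0) + (3 if self.random_slope else 1)

    def fit(self, maxiter: int = 500) -> "MixedCAR1Results":
        """Maximize the (restricted) likelihood; multi-start on (rho, scale)."""
        resid_sd = np.std(self.y - self.X @ np.linalg.lstsq(self.X, self.y, rcond=None)[0])
        resid_sd = max(resid_sd, 1e-3)
        base = np.zeros(self._n_theta())
        base[0] = np.log(resid_sd / np.sqrt(2))
        i_re = 1 + (1 if self.car1 else 0)
        base[i_re] = np.log(resid_sd / np.sqrt(2))
        if self.random_slope:
            base[i_re + 2] = np.log(resid_sd / 10)
        starts = [base.copy()]
        if self.car1:
            for z in (-6.0, 0.0):
                s = base.copy()
                s[1] = z
                starts.append(s)
        best = None
        for x0 in starts:
            res = optimize.minimize(lambda th: self._profiled(th)[0], x0,
                                    method="L-BFGS-B",
                                    options={"maxiter": maxiter, "ftol": 1e-13,
                                             "gtol": 1e-8})
            if best is None or res.fun < best.fun:
                best = res
        # Nelder-Mead polish: robust to the kinks L-BFGS sees at variance floors
        nm = optimize.minimize(lambda th: self._profiled(th)[0], best.x,
                               method="Nelder-Mead",
                               options={"maxiter": 400, "xatol": 1e-7,
                                        "fatol": 1e-10})
        if nm.fun < best.fun:
            best = nm
        converged = bool(np.isfinite(best.fun)) and best.fun < 1e9
        if not converged:
            warnings.warn("mixed-model optimization failed to converge",
                          ConvergenceWarning)
        nll, beta, cov_beta = self._profiled(best.x)
        sigma, rho, psi = self._unpack_theta(best.x)
        return MixedCAR1Results(model=self, params=beta, cov_params=cov_beta,
                                psi=psi, sigma=sigma, rho=rho,
                                loglik=-nll, theta=best.x, converged=converged)


@dataclass
class MixedCAR1Results:
    """Fitted fixed/random estimates with CIs, fit indices and diagnostics."""

    model: MixedCAR1Model
    params: np.ndarray
    cov_params: np.ndarray
    psi: np.ndarray
    sigma: float
    rho: float
    loglik: float
    theta: np.ndarray
    converged: bool
    #: analysis-frame (attached by fit_lmm) for standardization
    frame: pd.DataFrame | None = None
    spec: LmmSpec | None = None

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def df_resid(self) -> np.ndarray:
        """Per-coefficient t-test df: within terms use N - J - p1, between
        terms (incl. intercept and time) use J - p2 - 1."""
        m = self.model
        p1 = int(m.within_flags.sum())
        p2 = m.k_fe - p1
        df_w = max(m.n_obs - m.n_subjects - p1, 1)
        df_b = max(m.n_subjects - p2 - 1, 1)
        return np.where(m.within_flags, df_w, df_b).astype(float)

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * stats.t.sf(np.abs(self.tvalues), self.df_resid)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return np.column_stack([self.params - q * self.bse,
                                self.params + q * self.bse])

    @property
    def sd_intercept(self) -> float:
        return float(np.sqrt(self.psi[0, 0]))

    @property
    def sd_slope(self) -> float:
        return float(np.sqrt(self.psi[1, 1])) if self.psi.shape[0] > 1 else 0.0

    @property
    def aic(self) -> float:
        k = self.model.k_fe + self.model._n_theta()
        return -2 * self.loglik + 2 * k

    @property
    def bic(self) -> float:
        k = self.model.k_fe + self.model._n_theta()
        n = self.model.n_obs if self.model.method == "ML" else \
            self.model.n_obs - self.model.k_fe
        return -2 * self.loglik + k * np.log(n)

    def r2_nakagawa(self) -> tuple[float, float]:
        return r2_nakagawa(self)

    def icc(self) -> float:
        return icc(self)

    def standardized(self) -> pd.Series:
        return standardize_coefficients(self)

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        beta_std = self.standardized()
        df = pd.DataFrame({
            "coef": self.params, "se": self.bse,
            "ci_low": ci[:, 0], "ci_high": ci[:, 1],
            "beta_std": beta_std.to_numpy(),
            "t": self.tvalues, "df": self.df_resid, "p": self.pvalues,
        }, index=self.model.names)
        r2m, r2c = self.r2_nakagawa()
        df.attrs.update({
            "loglik": self.loglik, "aic": self.aic, "bic": self.bic,
            "sigma": self.sigma, "rho": self.rho,
            "sd_intercept": self.sd_intercept, "sd_slope": self.sd_slope,
            "icc": self.icc(), "r2_marginal": r2m, "r2_conditional": r2c,
            "n_obs": self.model.n_obs, "n_subjects": self.model.n_subjects,
            "method": self.model.method, "converged": self.converged,
        })
        return df


# ---------------------------------------------------------------------------
# model construction from ESM tables
# ---------------------------------------------------------------------------

def _build_frame(table: EsmTable, spec: LmmSpec) -> pd.DataFrame:
    df = table.with_derived()
    needed = {spec.outcome, *spec.within, *spec.between}
    src = {"log_bt": "bt_count", "people_total": "people_known"}
    base_cols = [src.get(c, c) for c in needed]
    table = filter_complete(table, sorted(set(base_cols)))
    df = table.with_derived()
    df = add_centered(df, sorted(set(spec.within) | set(spec.between)))
    if spec.lagged:
        lag_cols = [f"{c}_cwc" for c in spec.within] + ["t_days"]
        df = lag_predictors(df, lag_cols)
    return df


def fit_lmm(table: EsmTable, spec: LmmSpec | None = None) -> MixedCAR1Results:
    """Fit the within/between CAR(1) mixed model defined by ``spec``.

    Within predictors enter centered within cluster (lagged by one assessment
    when ``spec.lagged``); between predictors enter as grand-mean-centered
    subject means; time (days since the subject's first beep) carries the
    random slope.
    """
    spec = spec or LmmSpec()
    df = _build_frame(table, spec)
    lag = "_lag1" if spec.lagged else ""
    names = ["intercept"]
    cols = [np.ones(len(df))]
    flags = [False]
    for c in spec.within:
        names.append(f"{c}_cwc{lag}")
        cols.append(df[f"{c}_cwc{lag}"].to_numpy())
        flags.append(True)
    if spec.include_time:
        names.append(f"t_days{lag}")
        cols.append(df[f"t_days{lag}"].to_numpy())
        flags.append(True)
    for c in spec.between:
        names.append(f"{c}_cmc")
        cols.append(df[f"{c}_cmc"].to_numpy())
        flags.append(False)
    X = np.column_stack(cols)
    model = MixedCAR1Model(df[spec.outcome], X, names, df["subject_id"],
                           df[f"t_days{lag}"] if spec.lagged else df["t_days"],
                           within_flags=flags, random_slope=spec.random_slope,
                           car1=spec.car1, method=spec.method)
    res = model.fit()
    res.frame = df.iloc[model._order].reset_index(drop=True)
    res.spec = spec
    return res


def standardize_coefficients(results: MixedCAR1Results) -> pd.Series:
    """beta_std = B * SD(x) / SD(y) on the analysis sample.

    Predictor SDs are taken on the scale the predictor enters the model
    (centered/lagged); the intercept is left unstandardized (NaN).
    """
    m = results.model
    sd_y = np.std(m.y, ddof=1)
    out = []
    for k, name in enumerate(m.names):
        if name == "intercept":
            out.append(np.nan)
        else:
            out.append(results.params[k] * np.std(m.X[:, k], ddof=1) / sd_y)
    return pd.Series(out, index=m.names, name="beta_std")


def r2_nakagawa(results: MixedCAR1Results) -> tuple[float, float]:
    """Marginal and conditional R^2 (random-slope extension).

    var_f is the variance of the fixed-effect linear predictor; var_r is the
    mean over observations of ``z' Psi z`` evaluated at the observed times
    (intercept + slope contribution); var_e = sigma^2.
    """
    m = results.model
    var_f = float(np.var(m.X @ results.params))
    zz = []
    for sl in m._slices:
        Z = m._z(sl)
        zz.append(np.einsum("ij,jk,ik->i", Z, results.psi, Z))
    var_r = float(np.mean(np.concatenate(zz)))
    var_e = results.sigma ** 2
    tot = var_f + var_r + var_e
    return var_f / tot, (var_f + var_r) / tot


def icc(results: MixedCAR1Results) -> float:
    """Intraclass correlation: intercept variance over intercept + residual."""
    v0 = results.psi[0, 0]
    return float(v0 / (v0 + results.sigma ** 2))


def vif_report(table_or_results, spec: LmmSpec | None = None) -> pd.Series:
    """Variance inflation factors from the fixed-design correlation inverse."""
    if isinstance(table_or_results, MixedCAR1Results):
        m = table_or_results.model
        X = m.X[:, 1:]
        names = m.names[1:]
    else:
        res = fit_lmm(table_or_results, spec)
        return vif_report(res)
    R = np.corrcoef(X, rowvar=False)
    try:
        vif = np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        vif = np.full(X.shape[1], np.inf)
    return pd.Series(vif, index=names, name="VIF")


def validate_social_presence(table: EsmTable, method: str = "REML") -> MixedCAR1Results:
    """Bluetooth-validation model: log(people+1) ~ log(bt+1), random intercepts.

    Tests whether the log Bluetooth device count predicts the log-transformed
    self-reported people count; reports the standardized slope with CI.
    """
    table = filter_complete(table, ["bt_count", "people_known", "people_unknown"])
    df = table.with_derived()
    y = log1p_transform(df["people_total"])
    x = log1p_transform(df["bt_count"])
    X = np.column_stack([np.ones(len(df)), x])
    model = MixedCAR1Model(y, X, ["intercept", "log_bt"], df["subject_id"],
                           df["t_days"], within_flags=[False, True],
                           random_slope=False, car1=False, method=method)
    res = model.fit()
    res.frame = df.iloc[model._order].reset_index(drop=True)
    return res


# ---------------------------------------------------------------------------
# power simulation
# ---------------------------------------------------------------------------

def _fit_ri_ml(y: np.ndarray, x: np.ndarray, n_per_group: int):
    """Fast ML fit of y ~ x with a random intercept, balanced groups.

    Profiles the fixed effects and residual variance; a 1-D search over the
    variance ratio lambda = tau^2/sigma^2 uses the classic quasi-demeaning
    transform.  Returns (slope, slope_se, dof).
    """
    n = n_per_group
    J = y.size // n
    Y = y.reshape(J, n)
    Xm = x.reshape(J, n)

    def neg_ll(log_lam):
        lam = np.exp(log_lam)
        c = 1.0 - 1.0 / np.sqrt(1.0 + lam * n)
        yt = (Y - c * Y.mean(axis=1, keepdims=True)).ravel()
        xt = (Xm - c * Xm.mean(axis=1, keepdims=True)).ravel()
        ones_t = (1.0 - c) * np.ones_like(yt)
        D = np.column_stack([ones_t, xt])
        beta, *_ = np.linalg.lstsq(D, yt, rcond=None)
        rss = np.sum((yt - D @ beta) ** 2)
        N = yt.size
        sig2 = rss / N
        return 0.5 * (N * np.log(2 * np.pi * sig2) + N + J * np.log(1 + lam * n))

    res = optimize.minimize_scalar(neg_ll, bounds=(-10.0, 6.0), method="bounded",
                                   options={"xatol": 1e-8})
    lam = np.exp(res.x)
    c = 1.0 - 1.0 / np.sqrt(1.0 + lam * n)
    yt = (Y - c * Y.mean(axis=1, keepdims=True)).ravel()
    xt = (Xm - c * Xm.mean(axis=1, keepdims=True)).ravel()
    D = np.column_stack([(1.0 - c) * np.ones_like(yt), xt])
    DtD = D.T @ D
    beta = np.linalg.solve(DtD, D.T @ yt)
    N = yt.size
    sig2 = np.sum((yt - D @ beta) ** 2) / N
    cov = sig2 * np.linalg.inv(DtD)
    dof = N - J - 1
    return beta[1], np.sqrt(cov[1, 1]), dof


def power_simulation(n_subjects: int = 21, n_assessments: int = 42,
                     effect_r: float = 0.1, alpha: float = 0.05,
                     reps: int = 1000, seed: int = 0,
                     icc_target: float = 0.5) -> dict:
    """Monte-Carlo power for a within-person effect in a random-intercept LMM.

    Each replicate draws ``y_ij = effect_r * x_ij + u_j + e_ij`` with x
    standard normal within person, unit residual variance, and random
    intercept variance set by ``icc_target`` (0.5 gives unit variance).  The
    slope is tested at ``alpha``; power is the rejection fraction with a
    Wilson 95% interval.
    """
    if not -1 < effect_r < 1:
        raise ValueError("effect_r must be in (-1, 1)")
    if reps < 100:
        warnings.warn("fewer than 100 replicates: power CI will be wide")
    tau2 = icc_target / (1.0 - icc_target)
    rng = np.random.default_rng(seed)
    n_tot = n_subjects * n_assessments
    rejected = 0
    for _ in range(reps):
        x = rng.standard_normal(n_tot)
        u = np.repeat(rng.normal(0.0, np.sqrt(tau2), n_subjects), n_assessments)
        y = effect_r * x + u + rng.standard_normal(n_tot)
        slope, se, dof = _fit_ri_ml(y, x, n_assessments)
        pval = 2 * stats.t.sf(abs(slope / se), dof)
        rejected += pval < alpha
    power = rejected / reps
    z = stats.norm.ppf(0.975)
    denom = 1 + z ** 2 / reps
    center = (power + z ** 2 / (2 * reps)) / denom
    half = z * np.sqrt(power * (1 - power) / reps + z ** 2 / (4 * reps ** 2)) / denom
    return {"power": power, "ci_low": center - half, "ci_high": center + half,
            "reps": reps, "alpha": alpha}
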
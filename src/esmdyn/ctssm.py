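"""Continuous-time linear state-space (latent SDE) model with Kalman likelihood.

Two latent processes -- social presence (SP) and negative mood (NM) -- follow
a multivariate Ornstein-Uhlenbeck SDE

    d eta(t) = [A eta(t) + c + M chi(t)] dt + G dW(t),

where ``A`` is the drift matrix (negative diagonal: self-regulation;
off-diagonal: cross-effects), ``G`` the lower-triangular diffusion factor
(``G G^T`` is the diffusion matrix), and ``chi(t)`` a time-dependent covariate
(situational control) entering as an instantaneous impulse ``M chi`` at
observation times.  Five manifest indicators load on the latents through

    y(t) = Lambda eta(t) + tau + eps(t),     eps ~ N(0, diag(Theta)),

with row order (log Bluetooth count, fatigue, vigor, dejection, anger): the
Bluetooth indicator identifies SP with loading fixed to 1, the four emotion
scores load on NM with the vigor loading constrained negative.

Between irregularly spaced assessments the latent transition is exact:
``A_d = expm(A dt)``; the discrete innovation covariance comes from the
stationary solution of the Lyapunov equation ``A S + S A^T + G G^T = 0``.
Maximum likelihood uses a Kalman filter over every subject's series; derived
temporal quantities (half-lives of the auto-effects, the lag of the peak
cross-effect) are functionals of ``expm(A t)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from ._numdiff import wald_cov
from .data import EsmTable, filter_complete, log1p_transform

__all__ = [
    "CtssmParams",
    "CtssmModel",
    "CtssmResults",
    "discretize",
    "stationary_cov",
    "kalman_loglik",
    "half_life",
    "peak_cross_lag",
    "impulse_response",
    "fit_ctssm",
]

MANIFEST_ORDER = ["log_bt", "fatigue", "vigor", "dejection", "anger"]
LATENT_ORDER = ["SP", "NM"]
_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class CtssmParams:
    """Parameters of the two-process latent SDE with five indicators."""

    A: np.ndarray                     # 2x2 drift, diagonal < 0
    G: np.ndarray                     # 2x2 lower-triangular diffusion factor
    Lambda: np.ndarray                # 5x2 loadings; (0, 0) fixed to 1
    tau: np.ndarray                   # 5 manifest means
    theta: np.ndarray                 # 5 measurement-error variances
    t0_mean: np.ndarray               # 2 initial-state mean
    t0_cov: np.ndarray                # 2x2 initial-state covariance (PSD)
    c: np.ndarray = field(default_factory=lambda: np.zeros(2))  # continuous intercept
    M: np.ndarray = field(default_factory=lambda: np.zeros(2))  # impulse effect of control

    def __post_init__(self) -> None:
        for name in ("A", "G", "Lambda", "tau", "theta", "t0_mean", "t0_cov", "c", "M"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.A.shape != (2, 2) or self.G.shape != (2, 2) or self.Lambda.shape != (5, 2):
            raise ValueError("A and G must be 2x2, Lambda 5x2")
        if np.any(self.theta < 0):
            raise ValueError("measurement-error variances must be non-negative")
        ev = np.linalg.eigvals(self.t0_cov)
        if np.any(ev.real < -1e-10):
            raise ValueError("t0_cov must be positive semidefinite")

    @property
    def diffusion(self) -> np.ndarray:
        """Diffusion matrix ``G G^T``."""
        return self.G @ self.G.T

    def is_stable(self) -> bool:
        return bool(np.all(np.linalg.eigvals(self.A).real < 0))


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def stationary_cov(A: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Stationary latent covariance: solves ``A S + S A^T + G G^T = 0``."""
    A = np.asarray(A, dtype=float)
    if np.any(np.linalg.eigvals(A).real >= 0):
        raise ValueError("drift matrix must be stable (eigenvalue real parts < 0)")
    S = linalg.solve_continuous_lyapunov(A, -np.asarray(G) @ np.asarray(G).T)
    return 0.5 * (S + S.T)


def discretize(A, c, G, dt: float):
    """Exact discretization of the linear SDE over a gap of length ``dt``.

    Returns ``(A_d, c_d, Q_d)`` with ``A_d = expm(A dt)``,
    ``c_d = A^{-1} (A_d - I) c`` (series expansion if ``A`` is singular) and
    ``Q_d = S - A_d S A_d^T`` from the Lyapunov stationary covariance ``S``.
    ``Q_d`` is symmetrized and eigen-clipped at zero if round-off makes it
    indefinite.
    """
    A = np.asarray(A, dtype=float)
    c = np.zeros(A.shape[0]) if c is None else np.asarray(c, dtype=float)
    if dt < 0:
        raise ValueError("dt must be non-negative")
    Ad = linalg.expm(A * dt)
    if abs(np.linalg.det(A)) > 1e-12:
        cd = np.linalg.solve(A, (Ad - np.eye(A.shape[0])) @ c)
    else:
        # int_0^dt expm(A s) ds c by series
        term = dt * np.eye(A.shape[0])
        acc = term.copy()
        for k in range(1, 30):
            term = term @ A * (dt / (k + 1.0))
            acc += term
        cd = acc @ c
    S = stationary_cov(A, G)
    Qd = S - Ad @ S @ Ad.T
    Qd = 0.5 * (Qd + Qd.T)
    ev, U = np.linalg.eigh(Qd)
    if ev.min() < -1e-10 * max(1.0, ev.max()):
        warnings.warn("discretized innovation covariance indefinite; clipping", RuntimeWarning)
    if ev.min() < 0:
        Qd = (U * np.clip(ev, 0.0, None)) @ U.T
    return Ad, cd, Qd


def _discretize_many(A: np.ndarray, c: np.ndarray, S: np.ndarray, dts: np.ndarray):
    """Vectorized exact discretization over an array of gaps.

    Uses the eigendecomposition of the 2x2 drift so all gaps are handled at
    once: ``expm(A dt) = V diag(e^{lambda dt}) V^{-1}``.  ``S`` is the
    precomputed stationary covariance.  Returns arrays shaped
    ``dts.shape + (2, 2)`` / ``+ (2,)``.
    """
    lam, V = np.linalg.eig(A)
    Vinv = np.linalg.inv(V)
    e = np.exp(np.multiply.outer(dts, lam))            # (..., 2)
    Ad = np.einsum("ij,...j,jk->...ik", V, e, Vinv)
    Ad = Ad.real
    if np.any(np.abs(c) > 0):
        # A^{-1}(Ad - I) c via the same eigenbasis
        phi = (e - 1.0) / lam                           # (e^{l dt}-1)/l
        cd = np.einsum("ij,...j,jk,k->...i", V, phi, Vinv, c.astype(complex)).real
    else:
        cd = np.zeros(dts.shape + (2,))
    Qd = S - np.einsum("...ij,jk,...lk->...il", Ad, S, Ad)
    Qd = 0.5 * (Qd + np.swapaxes(Qd, -1, -2))
    return Ad, cd, Qd


# ---------------------------------------------------------------------------
# Kalman likelihood
# ---------------------------------------------------------------------------

def kalman_loglik(params: CtssmParams, subjects) -> float:
    """Exact Gaussian log-likelihood of per-subject series under the model.

    ``subjects`` is an iterable of ``(t, Y, chi)`` with ``t`` strictly
    increasing times (days), ``Y`` a ``(T, 5)`` array of manifests (NaN =
    missing, handled by dropping the corresponding measurement rows) and
    ``chi`` the control covariate applied as a state impulse ``M chi`` at each
    observation time before the measurement update.  Total log-likelihood sums
    over subjects; an empty series contributes 0.
    """
    if not params.is_stable():
        raise ValueError("drift matrix must be stable")
    total = 0.0
    S_inf = stationary_cov(params.A, params.G)
    for t, Y, chi in subjects:
        t = np.asarray(t, dtype=float)
        Y = np.asarray(Y, dtype=float)
        chi = np.zeros_like(t) if chi is None else np.asarray(chi, dtype=float)
        if t.size == 0:
            continue
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing within a subject")
        m = params.t0_mean.copy()
        P = params.t0_cov.copy()
        for k in range(t.size):
            if k > 0:
                dt = t[k] - t[k - 1]
                Ad, cd, Qd = _discretize_many(params.A, params.c, S_inf, np.array(dt))
                m = Ad @ m + cd
                P = Ad @ P @ Ad.T + Qd
            m = m + params.M * chi[k]
            obs = ~np.isnan(Y[k])
            if not obs.any():
                continue
            L = params.Lambda[obs]
            v = Y[k, obs] - (L @ m + params.tau[obs])
            Smat = L @ P @ L.T + np.diag(params.theta[obs])
            try:
                cf = linalg.cho_factor(Smat, lower=True)
            except linalg.LinAlgError as exc:
                raise ValueError(f"non-PSD innovation covariance; params={params}") from exc
            alpha = linalg.cho_solve(cf, v)
            logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
            total += -0.5 * (obs.sum() * _LOG2PI + logdet + v @ alpha)
            K = P @ L.T @ linalg.cho_solve(cf, np.eye(obs.sum()))
            m = m + K @ v
            P = P - K @ L @ P
            P = 0.5 * (P + P.T)
    return float(total)


def _batched_loglik(params: CtssmParams, dts, Y, chi, valid) -> float:
    """Vectorized Kalman log-likelihood over padded subject arrays.

    ``dts``: (S, T) gaps (0 at the first beep and for padding); ``Y``:
    (S, T, 5) with NaN for missing entries and padding; ``chi``: (S, T);
    ``valid``: (S, T) row-validity mask.  Exact missing-data handling relies
    on the diagonal measurement-error structure: masking a loading row and
    zeroing its residual decouples that coordinate, whose log-det/quadratic
    contribution is then subtracted in closed form.
    """
    S_inf = stationary_cov(params.A, params.G)
    Ad, cd, Qd = _discretize_many(params.A, params.c, S_inf, dts)   # (S,T,2,2) etc.
    nsub, T = dts.shape
    obs = valid[:, :, None] & ~np.isnan(Y)                          # (S,T,5)
    Y0 = np.where(obs, Y, 0.0)
    chi0 = np.where(valid, np.nan_to_num(chi), 0.0)
    m = np.broadcast_to(params.t0_mean, (nsub, 2)).copy()
    P = np.broadcast_to(params.t0_cov, (nsub, 2, 2)).copy()
    theta = params.theta
    Lam = params.Lambda
    total = 0.0
    eye5 = np.eye(5)
    for k in range(T):
        if k > 0:
            m = np.einsum("sij,sj->si", Ad[:, k], m) + cd[:, k]
            P = np.einsum("sij,sjk,slk->sil", Ad[:, k], P, Ad[:, k]) + Qd[:, k]
        m = m + params.M[None, :] * chi0[:, k, None]
        ob = obs[:, k]                                              # (S,5)
        Lmask = Lam[None, :, :] * ob[:, :, None]                    # (S,5,2)
        v = Y0[:, k] - (np.einsum("spj,sj->sp", Lmask, m) + params.tau[None, :])
        v = np.where(ob, v, 0.0)
        Smat = np.einsum("spj,sjk,sqk->spq", Lmask, P, Lmask) + (theta * eye5)[None, :, :]
        cf = np.linalg.cholesky(Smat)
        alpha = np.linalg.solve(Smat, v[..., None])[..., 0]
        logdet = 2.0 * np.sum(np.log(np.diagonal(cf, axis1=1, axis2=2)), axis=1)
        quad = np.einsum("sp,sp->s", v, alpha)
        nobs = ob.sum(axis=1)
        # remove the decoupled contribution of masked coordinates
        miss_logdet = np.einsum("sp,p->s", (~ob).astype(float), np.log(theta))
        ll = -0.5 * (nobs * _LOG2PI + (logdet - miss_logdet) + quad)
        total += ll.sum()
        K = np.einsum("sij,spj->sip", P, Lmask)
        K = np.linalg.solve(np.swapaxes(Smat, 1, 2), np.swapaxes(K, 1, 2))
        K = np.swapaxes(K, 1, 2)                                    # (S,2,5)
        m = m + np.einsum("sip,sp->si", K, v)
        P = P - np.einsum("sip,spj,sjk->sik", K, Lmask, P)
        P = 0.5 * (P + np.swapaxes(P, 1, 2))
    return float(total)


# ---------------------------------------------------------------------------
# derived temporal quantities
# ---------------------------------------------------------------------------

def impulse_response(A, horizon: float, step: float) -> pd.DataFrame:
    """``expm(A t)`` on a time grid; columns labelled ``<to><-<from>``."""
    A = np.asarray(A, dtype=float)
    ts = np.arange(0.0, horizon + 0.5 * step, step)
    lam, V = np.linalg.eig(A)
    Vinv = np.linalg.inv(V)
    E = np.einsum("ij,tj,jk->tik", V, np.exp(np.outer(ts, lam)), Vinv).real
    cols = {}
    for i, to in enumerate(LATENT_ORDER):
        for j, frm in enumerate(LATENT_ORDER):
            cols[f"{to}<-{frm}"] = E[:, i, j]
    return pd.DataFrame({"t_days": ts, **cols})


def half_life(A, index: int) -> float:
    """Smallest ``t > 0`` with the diagonal impulse response equal to 0.5.

    For a stable drift the auto-effect ``[expm(A t)]_{ii}`` starts at 1 and
    decays; the half-life is found by bracketing the first downward crossing
    of 0.5 and bisection (``brentq``) to 1e-8 days.
    """
    A = np.asarray(A, dtype=float)
    if np.any(np.linalg.eigvals(A).real >= 0):
        raise ValueError("drift matrix must be stable")

    def f(t):
        return linalg.expm(A * t)[index, index] - 0.5

    hi = 1e-3
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("auto-effect never reaches 0.5")
    lo = hi / 2.0 if hi > 1e-3 else 0.0
    while f(lo) < 0 and lo > 0:
        lo /= 2.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-8))


def peak_cross_lag(A, frm: int, to: int, horizon: float = 2.0) -> float:
    """Lag maximizing the magnitude of the cross impulse response.

    Evaluates ``|[expm(A t)]_{to, frm}|`` on a dense grid (1e-4 days over
    ``[0, horizon]``) and refines the best bracket with bounded golden-section
    search.  Raises if the cross-effect is identically zero.
    """
    A = np.asarray(A, dtype=float)
    if frm == to:
        raise ValueError("use half_life for auto-effects")
    ts = np.arange(0.0, horizon, 1e-4)
    lam, V = np.linalg.eig(A)
    Vinv = np.linalg.inv(V)
    vals = np.einsum("j,tj,j->t", V[to], np.exp(np.outer(ts, lam)), Vinv[:, frm]).real
    mags = np.abs(vals)
    if mags.max() < 1e-14:
        raise ValueError("no cross-effect: the relevant drift entry is zero")
    i = int(np.argmax(mags))
    lo = ts[max(i - 1, 0)]
    hi = ts[min(i + 1, ts.size - 1)]

    def negmag(t):
        return -abs(linalg.expm(A * t)[to, frm])

    res = optimize.minimize_scalar(negmag, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

def _pack_names():
    return [
        "a_sp_sp", "a_nm_nm", "a_sp_nm", "a_nm_sp",
        "m_sp", "m_nm",
        "log_g11", "z_g21",
        "lam_fatigue", "lam_vigor_neglog", "lam_dejection", "lam_anger",
        "tau_log_bt", "tau_fatigue", "tau_vigor", "tau_dejection", "tau_anger",
        "log_th_log_bt", "log_th_fatigue", "log_th_vigor", "log_th_dejection", "log_th_anger",
        "t0m_sp", "t0m_nm", "log_t0_l11", "t0_l21", "log_t0_l22",
    ]


def _unpack(x: np.ndarray) -> CtssmParams:
    """Map the unconstrained vector to model parameters.

    Constraints: diag(A) = -exp; vigor loading = -exp; Bluetooth loading on SP
    fixed to 1; NM diffusion variance (GG^T)_22 fixed to 1 for scale
    identification (g21 = tanh(z), g22 = sqrt(1 - g21^2)); Theta = exp; T0
    covariance via log-Cholesky.
    """
    a11 = -np.exp(x[0])
    a22 = -np.exp(x[1])
    A = np.array([[a11, x[2]], [x[3], a22]])
    M = np.array([x[4], x[5]])
    g11 = np.exp(x[6])
    g21 = np.tanh(x[7]) * 0.999
    g22 = np.sqrt(max(1.0 - g21 ** 2, 1e-12))
    G = np.array([[g11, 0.0], [g21, g22]])
    Lam = np.zeros((5, 2))
    Lam[0, 0] = 1.0
    Lam[1, 1] = x[8]
    Lam[2, 1] = -np.exp(x[9])
    Lam[3, 1] = x[10]
    Lam[4, 1] = x[11]
    tau = x[12:17].copy()
    theta = np.exp(x[17:22])
    t0_mean = x[22:24].copy()
    l11 = np.exp(x[24])
    l21 = x[25]
    l22 = np.exp(x[26])
    Lc = np.array([[l11, 0.0], [l21, l22]])
    t0_cov = Lc @ Lc.T
    return CtssmParams(A=A, G=G, Lambda=Lam, tau=tau, theta=theta,
                       t0_mean=t0_mean, t0_cov=t0_cov, M=M)


def _pack(p: CtssmParams) -> np.ndarray:
    x = np.empty(27)
    x[0] = np.log(-p.A[0, 0])
    x[1] = np.log(-p.A[1, 1])
    x[2] = p.A[0, 1]
    x[3] = p.A[1, 0]
    x[4:6] = p.M
    x[6] = np.log(p.G[0, 0])
    x[7] = np.arctanh(np.clip(p.G[1, 0] / 0.999, -0.999, 0.999))
    x[8] = p.Lambda[1, 1]
    x[9] = np.log(max(-p.Lambda[2, 1], 1e-6))
    x[10] = p.Lambda[3, 1]
    x[11] = p.Lambda[4, 1]
    x[12:17] = p.tau
    x[17:22] = np.log(np.maximum(p.theta, 1e-8))
    x[22:24] = p.t0_mean
    Lc = np.linalg.cholesky(p.t0_cov + 1e-10 * np.eye(2))
    x[24] = np.log(Lc[0, 0])
    x[25] = Lc[1, 0]
    x[26] = np.log(Lc[1, 1])
    return x


class CtssmModel:
    """ML estimation of the latent SDE from an :class:`EsmTable`.

    Manifest variables (log Bluetooth count and the four emotion sum scores)
    are z-standardized over all retained records before filtering; situational
    control enters as a state impulse at observation times.
    """

    def __init__(self, subjects, manifest_scale=None):
        # subjects: list of (t, Y(T,5), chi)
        self.subjects = subjects
        self.manifest_scale = manifest_scale
        Tmax = max((len(t) for t, _, _ in subjects), default=0)
        S = len(subjects)
        self._dts = np.zeros((S, Tmax))
        self._Y = np.full((S, Tmax, 5), np.nan)
        self._chi = np.zeros((S, Tmax))
        self._valid = np.zeros((S, Tmax), dtype=bool)
        for s, (t, Y, chi) in enumerate(subjects):
            T = len(t)
            if T == 0:
                continue
            self._dts[s, 1:T] = np.diff(t)
            self._Y[s, :T] = Y
            self._chi[s, :T] = 0.0 if chi is None else np.nan_to_num(chi)
            self._valid[s, :T] = True

    @classmethod
    def from_esm(cls, table: EsmTable, use_control: bool = True,
                 center_within_subject: bool = True) -> "CtssmModel":
        """Prepare z-scored manifests from an ESM table.

        With ``center_within_subject`` (default) each manifest is centered at
        the subject's own mean before standardization, so stable trait
        differences do not masquerade as extremely slow latent dynamics; the
        fitted drift then describes within-person fluctuation.
        """
        table = filter_complete(table, ["bt_count", *MANIFEST_ORDER[1:]] +
                                (["control"] if use_control else []))
        df = table.with_derived()
        cols = ["log_bt", "fatigue", "vigor", "dejection", "anger"]
        X = df[cols]
        if center_within_subject:
            X = X - X.groupby(df["subject_id"]).transform("mean")
        mu = X.mean()
        sd = X.std(ddof=0)
        Z = (X - mu) / sd
        ctrl = df["control"] if use_control else pd.Series(0.0, index=df.index)
        subjects = []
        for sid, idx in df.groupby("subject_id", sort=False).groups.items():
            t = df.loc[idx, "t_days"].to_numpy()
            subjects.append((t, Z.loc[idx].to_numpy(), ctrl.loc[idx].to_numpy()))
        return cls(subjects, manifest_scale=pd.DataFrame({"mean": mu, "sd": sd}))

    # -- likelihood ----------------------------------------------------

    def loglike(self, params: CtssmParams) -> float:
        if not params.is_stable():
            return -np.inf
        try:
            return _batched_loglik(params, self._dts, self._Y, self._chi, self._valid)
        except np.linalg.LinAlgError:
            return -np.inf

    def _negloglik(self, x: np.ndarray) -> float:
        try:
            p = _unpack(x)
        except (ValueError, FloatingPointError):
            return 1e10
        # smooth barrier at the stability boundary: a flat cliff stalls
        # quasi-Newton line searches, a slope steers them back
        stab = float(np.max(np.linalg.eigvals(p.A).real))
        if stab > -1e-4:
            return 1e7 * (1.0 + stab + 1e-4)
        ll = self.loglike(p)
        if not np.isfinite(ll):
            return 1e10
        return -ll

    def _start_vector(self, rng: np.random.Generator | None = None) -> np.ndarray:
        x = np.zeros(27)
        x[0] = x[1] = np.log(3.0)          # diag(A) = -3/day
        x[2], x[3] = -0.2, 0.2
        x[6] = np.log(2.0)
        x[8], x[10], x[11] = 0.6, 0.3, 0.3
        x[9] = np.log(0.5)
        x[17:22] = np.log(0.5)
        x[24] = x[26] = 0.0
        if rng is not None:
            x = x + rng.normal(0.0, 0.3, size=27)
        return x

    def fit(self, start: CtssmParams | None = None, n_starts: int = 5,
            seed: int = 0, maxiter: int = 400, compute_se: bool = True,
            triage_iter: int = 40) -> "CtssmResults":
        """Maximize the likelihood with seeded multi-start L-BFGS.

        Each start runs a short triage leg; the best continues to
        convergence (gradient-based stopping via L-BFGS defaults, ``maxiter``
        cap).  Wald SEs from a central-difference Hessian unless disabled.
        """
        rng = np.random.default_rng(seed)
        starts = []
        if start is not None:
            starts.append(_pack(start))
        starts.append(self._start_vector())
        while len(starts) < max(n_starts, 1):
            starts.append(self._start_vector(rng))
        best = None
        for x0 in starts:
            res = optimize.minimize(self._negloglik, x0, method="L-BFGS-B",
                                    options={"maxiter": triage_iter})
            if best is None or res.fun < best.fun:
                best = res
        final = optimize.minimize(self._negloglik, best.x, method="L-BFGS-B",
                                  options={"maxiter": maxiter, "ftol": 1e-11,
                                           "gtol": 1e-7})
        if final.fun > best.fun:
            final = best
        params = _unpack(final.x)
        cov = None
        if compute_se:
            with np.errstate(all="ignore"):
                cov = wald_cov(self._negloglik, final.x)
        return CtssmResults(model=self, params=params, x=final.x,
                            loglik=-final.fun, cov_x=cov,
                            converged=bool(final.success), n_starts=len(starts))


@dataclass
class CtssmResults:
    """Point estimates, likelihood and derived temporal quantities."""

    model: CtssmModel
    params: CtssmParams
    x: np.ndarray
    loglik: float
    cov_x: np.ndarray | None
    converged: bool
    n_starts: int

    @property
    def se_x(self) -> np.ndarray | None:
        if self.cov_x is None:
            return None
        d = np.diag(self.cov_x).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)

    def half_life(self, process: str = "NM") -> float:
        return half_life(self.params.A, LATENT_ORDER.index(process))

    def peak_cross_lag(self, frm: str = "SP", to: str = "NM") -> float:
        return peak_cross_lag(self.params.A, LATENT_ORDER.index(frm),
                              LATENT_ORDER.index(to))

    def impulse_response(self, horizon: float = 1.0, step: float = 0.01) -> pd.DataFrame:
        return impulse_response(self.params.A, horizon, step)

    def standardized_params(self) -> CtssmParams:
        """Rescale the NM latent to unit stationary variance.

        A diagonal similarity transform ``D = diag(1, s)`` leaves the SP scale
        (pinned by the unit Bluetooth loading) alone and maps loadings,
        impulse effects and diffusion consistently; auto-effect half-lives are
        invariant.
        """
        S = stationary_cov(self.params.A, self.params.G)
        s = 1.0 / np.sqrt(S[1, 1])
        D = np.diag([1.0, s])
        Dinv = np.diag([1.0, 1.0 / s])
        A = D @ self.params.A @ Dinv
        G = D @ self.params.G
        Lam = self.params.Lambda @ Dinv
        M = D @ self.params.M
        t0m = D @ self.params.t0_mean
        t0c = D @ self.params.t0_cov @ D.T
        return replace(self.params, A=A, G=G, Lambda=Lam, M=M,
                       t0_mean=t0m, t0_cov=t0c)

    def summary(self) -> pd.DataFrame:
        names = _pack_names()
        p = self.params
        natural = {
            "a_sp_sp": p.A[0, 0], "a_nm_nm": p.A[1, 1],
            "a_sp_nm": p.A[0, 1], "a_nm_sp": p.A[1, 0],
            "m_sp": p.M[0], "m_nm": p.M[1],
            "log_g11": p.G[0, 0], "z_g21": p.G[1, 0],
            "lam_fatigue": p.Lambda[1, 1], "lam_vigor_neglog": p.Lambda[2, 1],
            "lam_dejection": p.Lambda[3, 1], "lam_anger": p.Lambda[4, 1],
        }
        rows = []
        se = self.se_x
        for i, n in enumerate(names):
            rows.append({
                "parameter": n,
                "estimate_natural": natural.get(n, np.nan),
                "estimate_unconstrained": self.x[i],
                "se_unconstrained": np.nan if se is None else se[i],
            })
        df = pd.DataFrame(rows)
        df.attrs["loglik"] = self.loglik
        df.attrs["converged"] = self.converged
        return df


def fit_ctssm(table: EsmTable, init: CtssmParams | None = None, **options) -> CtssmResults:
    """Convenience wrapper: build :class:`CtssmModel` from a table and fit."""
    return CtssmModel.from_esm(table).fit(start=init, **options)
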
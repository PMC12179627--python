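"""Synthetic experience-sampling data with the structure the analyses assume.

The generators emulate a two-week smartphone ESM study: ~80 subjects prompted
four times a day with ~77% compliance and jittered prompt times; right-skewed
Bluetooth device counts whose log(x+1) is well behaved; four emotion scales
built from four 1-4 Likert items each; a bivariate latent
Ornstein-Uhlenbeck system (social presence <-> negative mood) with
bidirectional drift driving the observables; and, for the state-switching
analysis, a continuous-time two-state Markov regime with zero-inflated
negative-binomial emission of shifted sum scores.

Default dynamic parameters are illustrative values in the neighbourhood of
the fitted models this package targets; they are stored here as plain
dataclass defaults, not fitted claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctssm import _discretize_many, stationary_cov
from .data import CONSTRUCTS, EsmTable, ItemTable, log1p_transform

__all__ = [
    "DesignConfig",
    "OuGeneratorParams",
    "GtheoryGeneratorParams",
    "CthmmGeneratorParams",
    "generate_design",
    "simulate_control",
    "simulate_latent_ou",
    "emit_observations",
    "generate_dataset",
    "simulate_items",
    "simulate_ctmc",
    "simulate_cthmm",
    "generate_cthmm_dataset",
]

#: prompt slots within a day (9:00, 13:00, 17:00, 21:00), in days
_SLOTS = np.array([9.0, 13.0, 17.0, 21.0]) / 24.0


@dataclass
class DesignConfig:
    """Sampling design: who is beeped when, and how often they answer."""

    n_subjects: int = 80
    n_days: int = 14
    beeps_per_day: int = 4
    compliance: float = 0.768
    time_jitter_sd: float = 0.015   # days (~22 min)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.compliance <= 1):
            raise ValueError("compliance must be in (0, 1]")
        if min(self.n_subjects, self.n_days, self.beeps_per_day) <= 0:
            raise ValueError("design sizes must be positive")


def generate_design(cfg: DesignConfig) -> pd.DataFrame:
    """Per-subject beep schedule with jitter and compliance thinning.

    Returns columns ``subject_id, beep_index, t_days``; times are rebased so
    each subject's first *answered* beep is at t = 0 and strictly increase.
    Jitter large enough to reorder beeps triggers a re-sort.
    """
    rng = np.random.default_rng(cfg.seed)
    slots = _SLOTS[:cfg.beeps_per_day] if cfg.beeps_per_day <= 4 else \
        (np.arange(cfg.beeps_per_day) + 0.5) / cfg.beeps_per_day
    rows = []
    for s in range(cfg.n_subjects):
        sid = f"S{s:03d}"
        base = (np.arange(cfg.n_days)[:, None] + slots[None, :]).ravel()
        t = base + rng.normal(0.0, cfg.time_jitter_sd, size=base.size)
        if np.any(np.diff(t) <= 0):
            t = np.sort(t)
        keep = rng.random(base.size) < cfg.compliance
        t = t[keep]
        if t.size == 0:
            continue
        t = t - t[0]
        for k, tk in enumerate(t):
            rows.append((sid, k, tk))
    return pd.DataFrame(rows, columns=["subject_id", "beep_index", "t_days"])


# ---------------------------------------------------------------------------
# OU latent system and observation model
# ---------------------------------------------------------------------------

@dataclass
class OuGeneratorParams:
    """Latent SDE and emission parameters for the main ESM generator.

    Latent order (SP, NM); manifest order (log_bt, fatigue, vigor, dejection,
    anger).  The drift/diffusion/covariate defaults sit near the dynamics this
    package is designed to estimate: strong self-regulation, positive SP->NM
    and negative NM->SP cross-effects, and a negative instantaneous effect of
    situational control on both latents.
    """

    A: np.ndarray = field(default_factory=lambda: np.array([[-7.98, -1.42],
                                                            [3.04, -5.54]]))
    G: np.ndarray = field(default_factory=lambda: np.array([[2.55, 0.0],
                                                            [-0.08, 3.01]]))
    M: np.ndarray = field(default_factory=lambda: np.array([-0.19, -0.08]))
    Lambda: np.ndarray = field(default_factory=lambda: np.array(
        [[1.0, 0.0], [0.0, 0.68], [0.0, -0.58], [0.0, 0.18], [0.0, 0.13]]))
    tau: np.ndarray = field(default_factory=lambda: np.zeros(5))
    theta: np.ndarray = field(default_factory=lambda: np.array(
        [0.25, 0.32, 0.55, 0.44, 0.76]))
    t0_mean: np.ndarray = field(default_factory=lambda: np.array([-0.18, 0.59]))
    t0_cov: np.ndarray = field(default_factory=lambda: np.array([[0.56, -0.03],
                                                                 [-0.03, 1.12]]))
    #: Bluetooth count emission: log-mean = b0 + b1 * eta_SP; NB dispersion r
    bt_link: tuple = (2.2, 0.9, 0.6)
    #: people_total emission: Poisson log-mean = c0 + c1 * log1p(bt_count)
    people_link: tuple = (-0.8, 0.55)
    #: item intercepts per construct (centers of the 1-4 Likert scale)
    item_intercepts: dict = field(default_factory=lambda: {
        "vigor": 2.4, "fatigue": 2.0, "dejection": 1.5, "anger": 1.3})
    item_noise_sd: float = 0.5
    #: stable trait differences: per-subject intercept SDs (shared across a
    #: construct's items, hence "person" variance in the G-study sense)
    subject_sd_emotion: dict = field(default_factory=lambda: {
        "vigor": 0.55, "fatigue": 0.6, "dejection": 0.5, "anger": 0.4})
    #: per-subject offset SD on the Bluetooth log-mean (between-person ICC)
    subject_sd_bt: float = 1.2
    #: situational-control latent OU: (mean-reversion rate /day, stationary sd, mean logit)
    control_process: tuple = (2.0, 1.0, 0.8)
    #: covariate hold: "impulse" (instantaneous at beeps) or "hold" (zero-order)
    covariate_mode: str = "impulse"

    def __post_init__(self) -> None:
        for name in ("A", "G", "M", "Lambda", "tau", "theta", "t0_mean", "t0_cov"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.linalg.eigvals(self.A).real >= 0):
            raise ValueError("drift matrix A must be stable")
        if np.any(self.theta < 0):
            raise ValueError("measurement-error variances must be non-negative")
        if np.any(np.linalg.eigvalsh(0.5 * (self.t0_cov + self.t0_cov.T)) < -1e-10):
            raise ValueError("t0_cov must be PSD")


def simulate_control(schedule: pd.DataFrame, params: OuGeneratorParams,
                     seed: int) -> pd.Series:
    """Bounded situational-control series in [0, 1] at beep times.

    A scalar OU process on the logit scale, evaluated at the (irregular) beep
    times with exact transitions, pushed through the logistic function.
    """
    kappa, sd, mu = params.control_process
    rng = np.random.default_rng(seed)
    out = np.empty(len(schedule))
    pos = 0
    for _, g in schedule.groupby("subject_id", sort=False):
        t = g["t_days"].to_numpy()
        x = rng.normal(mu, sd)
        out[pos] = x
        for k in range(1, t.size):
            a = np.exp(-kappa * (t[k] - t[k - 1]))
            x = mu + a * (x - mu) + rng.normal(0.0, sd * np.sqrt(1.0 - a * a))
            out[pos + k] = x
        pos += t.size
    return pd.Series(1.0 / (1.0 + np.exp(-out)), index=schedule.index, name="control")


def simulate_latent_ou(params: OuGeneratorParams, schedule: pd.DataFrame,
                       control: pd.Series | None, seed: int) -> np.ndarray:
    """Latent (SP, NM) paths at beep times by exact Gaussian transitions.

    Between consecutive beeps the state propagates with mean ``expm(A dt) eta``
    and covariance ``S - expm(A dt) S expm(A dt)^T`` (``S`` the Lyapunov
    stationary covariance); the control covariate adds an instantaneous
    impulse ``M chi`` at each beep.  Returns an ``(n_rows, 2)`` array aligned
    with the schedule.
    """
    if np.any(np.linalg.eigvals(params.A).real >= 0):
        raise ValueError("drift matrix A must be stable")
    rng = np.random.default_rng(seed)
    S = stationary_cov(params.A, params.G)
    chi = np.zeros(len(schedule)) if control is None else np.asarray(control, dtype=float)
    eta = np.empty((len(schedule), 2))
    Lt0 = np.linalg.cholesky(params.t0_cov + 1e-12 * np.eye(2))
    pos = 0
    for _, g in schedule.groupby("subject_id", sort=False):
        t = g["t_days"].to_numpy()
        dts = np.diff(t)
        Ad, _, Qd = _discretize_many(params.A, np.zeros(2), S, dts)
        x = params.t0_mean + Lt0 @ rng.standard_normal(2)
        x = x + params.M * chi[pos]
        eta[pos] = x
        for k in range(dts.size):
            Q = Qd[k]
            L = np.linalg.cholesky(Q + 1e-12 * np.eye(2))
            x = Ad[k] @ x + L @ rng.standard_normal(2)
            x = x + params.M * chi[pos + 1 + k]
            eta[pos + 1 + k] = x
        pos += t.size
    return eta


def emit_observations(latent: np.ndarray, schedule: pd.DataFrame,
                      control: pd.Series, params: OuGeneratorParams,
                      seed: int) -> tuple[EsmTable, ItemTable]:
    """Observable ESM rows (and item-level responses) from latent paths.

    Emotion items: ``round(clip(intercept + loading * eta_NM + noise, 1, 4))``
    summed over 4 items to the 4-16 sum score.  Bluetooth counts are negative
    binomial with log-mean linked to eta_SP (right-skewed: mean >> median);
    people counts are Poisson with log-mean linked to log(bt+1), split
    into known/unknown; control is recorded as given.
    """
    rng = np.random.default_rng(seed)
    n = len(schedule)
    eta_sp, eta_nm = latent[:, 0], latent[:, 1]
    subj_codes = pd.factorize(schedule["subject_id"])[0]
    n_subj = subj_codes.max() + 1

    b0, b1, r_disp = params.bt_link
    bt_offset = rng.normal(0.0, params.subject_sd_bt, n_subj)[subj_codes]
    mean_bt = np.exp(b0 + b1 * eta_sp + bt_offset)
    bt = rng.negative_binomial(r_disp, r_disp / (r_disp + mean_bt))

    c0, c1 = params.people_link
    mean_people = np.exp(c0 + c1 * log1p_transform(bt))
    people_total = rng.poisson(mean_people)
    people_known = rng.binomial(people_total, 0.5)

    #: loadings by construct, from the NM column of Lambda
    lam = {"fatigue": params.Lambda[1, 1], "vigor": params.Lambda[2, 1],
           "dejection": params.Lambda[3, 1], "anger": params.Lambda[4, 1]}
    item_offsets = np.array([-0.2, -0.05, 0.05, 0.2])
    esm = schedule.copy()
    item_rows = []
    for c in CONSTRUCTS:
        icpt = params.item_intercepts[c]
        trait = rng.normal(0.0, params.subject_sd_emotion[c], n_subj)[subj_codes]
        resp = np.empty((n, 4), dtype=int)
        for j in range(4):
            raw = icpt + item_offsets[j] + trait + lam[c] * eta_nm + \
                rng.normal(0.0, params.item_noise_sd, size=n)
            resp[:, j] = np.clip(np.round(raw), 1, 4).astype(int)
        esm[c] = resp.sum(axis=1)
        for j in range(4):
            item_rows.append(pd.DataFrame({
                "subject_id": schedule["subject_id"].to_numpy(),
                "occasion_index": schedule["beep_index"].to_numpy(),
                "construct": c,
                "item_index": j + 1,
                "response": resp[:, j],
            }))
    esm["bt_count"] = bt
    esm["people_known"] = people_known
    esm["people_unknown"] = people_total - people_known
    esm["control"] = np.asarray(control, dtype=float)
    return EsmTable(esm), ItemTable(pd.concat(item_rows, ignore_index=True))


def simulate_ctssm_manifest(params, schedule: pd.DataFrame,
                            control: pd.Series | None, seed: int) -> np.ndarray:
    """Gaussian manifest observations ``y = Lambda eta + tau + N(0, Theta)``.

    ``params`` may be any object with the latent SDE fields (A, G, M,
    t0_mean, t0_cov) plus Lambda/tau/theta -- in particular a
    :class:`esmdyn.ctssm.CtssmParams`.  Used for known-truth recovery of the
    state-space estimator under its own measurement model.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    latent = simulate_latent_ou(params, schedule, control,
                                int(ss[0].generate_state(1)[0] % 2**31))
    rng = np.random.default_rng(int(ss[1].generate_state(1)[0] % 2**31))
    Lam = np.asarray(params.Lambda, float)
    tau = np.asarray(params.tau, float)
    theta = np.asarray(params.theta, float)
    noise = rng.standard_normal((len(schedule), Lam.shape[0])) * np.sqrt(theta)
    return latent @ Lam.T + tau + noise


def generate_dataset(cfg: DesignConfig | None = None,
                     params: OuGeneratorParams | None = None,
                     seed: int = 0) -> tuple[EsmTable, ItemTable]:
    """End-to-end generator: design -> control -> latent OU -> observables.

    Sub-stream seeds are derived deterministically from ``seed``.
    """
    cfg = cfg if cfg is not None else DesignConfig(seed=seed)
    params = params if params is not None else OuGeneratorParams()
    ss = np.random.SeedSequence(seed).spawn(3)
    cfg = DesignConfig(**{**cfg.__dict__, "seed": int(ss[0].generate_state(1)[0] % 2**31)})
    schedule = generate_design(cfg)
    control = simulate_control(schedule, params, int(ss[1].generate_state(1)[0] % 2**31))
    s2 = int(ss[2].generate_state(1)[0] % 2**31)
    latent = simulate_latent_ou(params, schedule, control, s2)
    return emit_observations(latent, schedule, control, params, s2 + 1)


# ---------------------------------------------------------------------------
# G-theory item generator
# ---------------------------------------------------------------------------

@dataclass
class GtheoryGeneratorParams:
    """Variance components of a fully crossed person x item x occasion design."""

    var_p: float = 1.0
    var_i: float = 0.05
    var_o: float = 0.05
    var_pi: float = 0.1
    var_po: float = 0.8
    var_io: float = 0.0
    var_res: float = 0.5
    mu: float = 2.0

    def components(self) -> dict:
        return {"p": self.var_p, "i": self.var_i, "o": self.var_o,
                "pi": self.var_pi, "po": self.var_po, "io": self.var_io,
                "res": self.var_res}

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.components().values()):
            raise ValueError("variance components must be non-negative")


def simulate_items(params: GtheoryGeneratorParams, n_subjects: int,
                   n_items: int, n_occasions: int, seed: int,
                   discretize: bool = False):
    """Gaussian crossed-effects responses; optionally discretized to 1-4.

    Returns an :class:`ItemTable` when ``discretize`` is set (valid Likert
    responses), otherwise a plain DataFrame with the same columns and
    continuous responses (the form used for estimator-recovery checks).
    """
    rng = np.random.default_rng(seed)
    sd = {k: np.sqrt(v) for k, v in params.components().items()}
    p_eff = rng.normal(0, sd["p"], n_subjects)
    i_eff = rng.normal(0, sd["i"], n_items)
    o_eff = rng.normal(0, sd["o"], n_occasions)
    pi_eff = rng.normal(0, sd["pi"], (n_subjects, n_items))
    po_eff = rng.normal(0, sd["po"], (n_subjects, n_occasions))
    io_eff = rng.normal(0, sd["io"], (n_items, n_occasions))
    res = rng.normal(0, sd["res"], (n_subjects, n_items, n_occasions))
    y = (params.mu + p_eff[:, None, None] + i_eff[None, :, None] +
         o_eff[None, None, :] + pi_eff[:, :, None] + po_eff[:, None, :] +
         io_eff[None, :, :] + res)
    P, I, O = np.meshgrid(np.arange(n_subjects), np.arange(n_items),
                          np.arange(n_occasions), indexing="ij")
    df = pd.DataFrame({
        "subject_id": [f"S{k:03d}" for k in P.ravel()],
        "occasion_index": O.ravel(),
        "construct": "vigor",
        "item_index": I.ravel() + 1,
        "response": y.ravel(),
    })
    if discretize:
        df["response"] = np.clip(np.round(df["response"]), 1, 4).astype(int)
        return ItemTable(df)
    return df


# ---------------------------------------------------------------------------
# continuous-time two-state regime generator
# ---------------------------------------------------------------------------

@dataclass
class CthmmGeneratorParams:
    """Two-state continuous-time Markov regime with ZINB score emissions.

    State 1 is the vigorous regime, state 2 the fatigued one.  Baseline
    intensities are per day; covariates scale them as
    ``q_12 = alpha_12 exp(beta_12 z_bt)`` and
    ``q_21 = alpha_21 exp(beta_21 z_ctrl)``.  Emission triplets ``(r, p, pi)``
    index ``[state, construct]`` with construct order (vigor, fatigue,
    dejection, anger) and generate shifted sum scores (0-12).
    """

    alpha_12: float = 1.0 / 10.72
    alpha_21: float = 1.0 / 6.20
    beta_12: float = float(np.log(1.25))
    beta_21: float = float(np.log(1.25))
    r: np.ndarray = field(default_factory=lambda: np.array(
        [[10.46, 1.80, 1.26, 0.14], [7.20, 7.93, 2.67, 2.02]]))
    p: np.ndarray = field(default_factory=lambda: np.array(
        [[0.44, 0.25, 0.48, 0.16], [0.44, 0.41, 0.25, 0.32]]))
    pi: np.ndarray = field(default_factory=lambda: np.array(
        [[0.01, 0.15, 0.51, 0.20], [0.01, 0.00, 0.00, 0.21]]))
    initial: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))

    def __post_init__(self) -> None:
        for name in ("r", "p", "pi", "initial"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.alpha_12 < 0 or self.alpha_21 < 0:
            raise ValueError("baseline intensities must be non-negative")
        if np.any(self.r <= 0) or np.any((self.p <= 0) | (self.p >= 1)) or \
                np.any((self.pi < 0) | (self.pi >= 1)):
            raise ValueError("ZINB parameters out of domain")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")


def simulate_ctmc(q12: float, q21: float, t_max: float, rng,
                  start: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Exact trajectory of the two-state chain: (jump times, states).

    ``states[k]`` holds on ``[times[k], times[k+1])``; the last state holds to
    ``t_max``.  A zero intensity makes the state absorbing.
    """
    t, s = 0.0, start
    times, states = [0.0], [start]
    rates = (q12, q21)
    while True:
        rate = rates[s]
        if rate <= 0:
            break
        t = t + rng.exponential(1.0 / rate)
        if t >= t_max:
            break
        s = 1 - s
        times.append(t)
        states.append(s)
    return np.array(times), np.array(states, dtype=int)


def _zinb_draw(rng, r, p, pi, size):
    """ZINB draws with NB success probability ``p`` (mass ~ (1-p)^r p^y)."""
    nb = rng.negative_binomial(r, 1.0 - p, size=size)
    zero = rng.random(size) < pi
    return np.where(zero, 0, nb)


def simulate_cthmm(params: CthmmGeneratorParams, schedule: pd.DataFrame,
                   covariates: pd.DataFrame | None, seed: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Regime paths at beeps and shifted (0-12) scores per construct.

    The chain runs in continuous time with piecewise-constant intensities
    between beeps, using the covariates observed at the earlier assessment
    (observation-carried-forward).  Returns ``(states, scores)`` aligned with
    the schedule rows; ``scores`` has columns in construct order (vigor,
    fatigue, dejection, anger).
    """
    rng = np.random.default_rng(seed)
    n = len(schedule)
    if covariates is None:
        z_bt = np.zeros(n)
        z_ctrl = np.zeros(n)
    else:
        z_bt = covariates["z_bt"].to_numpy(dtype=float)
        z_ctrl = covariates["z_ctrl"].to_numpy(dtype=float)
    states = np.empty(n, dtype=int)
    pos = 0
    for _, g in schedule.groupby("subject_id", sort=False):
        t = g["t_days"].to_numpy()
        s = int(rng.choice(2, p=params.initial))
        states[pos] = s
        for k in range(1, t.size):
            q12 = params.alpha_12 * np.exp(params.beta_12 * z_bt[pos + k - 1])
            q21 = params.alpha_21 * np.exp(params.beta_21 * z_ctrl[pos + k - 1])
            _, traj = simulate_ctmc(q12, q21, t[k] - t[k - 1], rng, start=s)
            s = int(traj[-1])
            states[pos + k] = s
        pos += t.size
    scores = np.empty((n, 4), dtype=int)
    for s in (0, 1):
        idx = states == s
        for j in range(4):
            scores[idx, j] = _zinb_draw(rng, params.r[s, j], params.p[s, j],
                                        params.pi[s, j], int(idx.sum()))
    return states, scores


def generate_cthmm_dataset(cfg: DesignConfig | None = None,
                           params: CthmmGeneratorParams | None = None,
                           seed: int = 0) -> pd.DataFrame:
    """Schedule plus regime states, shifted scores, and standardized covariates.

    Covariates are drawn as independent standard normals per beep (a
    stand-in for z-scored log Bluetooth count and control) so that intensity
    effects are identifiable in recovery studies.
    """
    cfg = cfg if cfg is not None else DesignConfig(seed=seed)
    params = params if params is not None else CthmmGeneratorParams()
    ss = np.random.SeedSequence(seed).spawn(3)
    cfg = DesignConfig(**{**cfg.__dict__, "seed": int(ss[0].generate_state(1)[0] % 2**31)})
    schedule = generate_design(cfg)
    rng = np.random.default_rng(int(ss[1].generate_state(1)[0] % 2**31))
    cov = pd.DataFrame({"z_bt": rng.standard_normal(len(schedule)),
                        "z_ctrl": rng.standard_normal(len(schedule))},
                       index=schedule.index)
    states, scores = simulate_cthmm(params, schedule, cov,
                                    int(ss[2].generate_state(1)[0] % 2**31))
    out = schedule.copy()
    out["state"] = states
    for j, c in enumerate(CONSTRUCTS):
        out[f"{c}_shifted"] = scores[:, j]
    out[["z_bt", "z_ctrl"]] = cov
    return out
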
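"""Hidden two-state continuous-time Markov model with ZINB emissions."""

import itertools

import numpy as np
import pytest

from esmdyn.cthmm import (
    CthmmModel,
    CthmmParams,
    forward_backward,
    forward_loglik,
    hazard_ratios,
    intensity_matrix,
    mean_sojourn,
    state_profiles,
    transition_probability,
    viterbi_decode,
    zinb_logpmf,
    zinb_mean,
    zinb_pmf,
)
from scipy import linalg


def _random_cthmm(rng) -> CthmmParams:
    return CthmmParams(
        alpha_12=float(rng.uniform(0.1, 1.0)),
        alpha_21=float(rng.uniform(0.1, 1.0)),
        beta_12=float(rng.normal(0, 0.4)), beta_21=float(rng.normal(0, 0.4)),
        r=rng.uniform(0.3, 6, (2, 4)), p=rng.uniform(0.15, 0.7, (2, 4)),
        pi=rng.uniform(0, 0.5, (2, 4)),
        rho0=np.array([0.6, 0.4]))


def _random_series(rng, T):
    t = np.concatenate([[0.0], np.cumsum(rng.uniform(0.2, 0.6, T - 1))])
    scores = rng.integers(0, 10, (T, 4)).astype(float)
    return (t, scores, rng.normal(0, 1, T), rng.normal(0, 1, T))


class TestZinb:
    def test_pure_zero_inflation(self):
        assert zinb_pmf(0, 2.0, 0.5, 1.0 - 1e-12) == pytest.approx(1.0)

    def test_geometric_special_case(self):
        # r = 1, pi = 0 reduces to geometric: (1-p) p^y
        assert zinb_pmf(2, 1.0, 0.5, 0.0) == pytest.approx(0.125, abs=1e-12)

    def test_vigorous_state_dejection_zero_mass(self):
        """Fitted-magnitude ZINB (r=1.26, p=0.48, pi=0.51) puts ~0.725 at 0."""
        val = zinb_pmf(0, 1.26, 0.48, 0.51)
        assert val == pytest.approx(0.51 + 0.49 * 0.52 ** 1.26, abs=1e-12)
        assert val == pytest.approx(0.725, abs=1e-3)

    def test_mass_sums_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            r, p, pi = rng.uniform(0.2, 8), rng.uniform(0.1, 0.8), rng.uniform(0, 0.8)
            total = zinb_pmf(np.arange(3000), r, p, pi).sum()
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            zinb_pmf(1, -1.0, 0.5, 0.0)
        with pytest.raises(ValueError):
            zinb_pmf(1, 1.0, 1.5, 0.0)

    def test_mean_formula(self):
        assert zinb_mean(2.0, 0.5, 0.0) == pytest.approx(2.0)
        assert zinb_mean(2.0, 0.5, 0.999999999) == pytest.approx(0.0, abs=1e-6)


class TestIntensityAndTransitions:
    def test_baseline_at_zero_covariates(self):
        p = CthmmParams(alpha_12=0.3, alpha_21=0.6, beta_12=0.5, beta_21=-0.5)
        Q = intensity_matrix(p, 0.0, 0.0)
        assert Q[0, 1] == pytest.approx(0.3) and Q[1, 0] == pytest.approx(0.6)

    def test_hazard_ratio_scales_intensity(self):
        p = CthmmParams(alpha_12=0.3, alpha_21=0.6, beta_12=np.log(1.25))
        Q = intensity_matrix(p, z_bt=1.0)
        assert Q[0, 1] == pytest.approx(0.3 * 1.25, abs=1e-12)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            Q = intensity_matrix(_random_cthmm(rng), rng.normal(), rng.normal())
            assert np.allclose(Q.sum(axis=1), 0, atol=1e-14)

    def test_zero_gap_is_identity(self):
        Q = np.array([[-0.3, 0.3], [0.6, -0.6]])
        assert np.allclose(transition_probability(Q, 0.0), np.eye(2))

    def test_closed_form_matches_expm(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            q12, q21 = rng.uniform(0.01, 3, 2)
            Q = np.array([[-q12, q12], [q21, -q21]])
            dt = rng.uniform(0.01, 5)
            assert np.allclose(transition_probability(Q, dt),
                               linalg.expm(Q * dt), atol=1e-12)

    def test_printed_sojourn_times_give_one_day_probabilities(self):
        """Sojourns of 10.72 / 6.20 days imply one-day P = 0.92/0.08/0.14/0.86."""
        Q = np.array([[-1 / 10.72, 1 / 10.72], [1 / 6.20, -1 / 6.20]])
        P = transition_probability(Q, 1.0)
        assert np.round(P, 2).tolist() == [[0.92, 0.08], [0.14, 0.86]]

    def test_long_run_rows_approach_stationary(self):
        q12, q21 = 0.4, 0.9
        Q = np.array([[-q12, q12], [q21, -q21]])
        P = transition_probability(Q, 1e6)
        stat = np.array([q21, q12]) / (q12 + q21)
        assert np.allclose(P, np.vstack([stat, stat]), atol=1e-12)

    def test_semigroup_property(self):
        Q = np.array([[-0.25, 0.25], [0.4, -0.4]])
        P1 = transition_probability(Q, 0.7)
        P2 = transition_probability(Q, 1.1)
        assert np.allclose(P1 @ P2, transition_probability(Q, 1.8), atol=1e-12)

    def test_mean_sojourn(self):
        Q = np.array([[-0.0933, 0.0933], [1.0, -1.0]])
        so = mean_sojourn(Q)
        assert so[0] == pytest.approx(10.72, abs=0.01)
        assert so[1] == pytest.approx(1.0)
        assert mean_sojourn(2 * Q)[0] == pytest.approx(so[0] / 2)

    def test_hazard_ratio_report(self):
        p = CthmmParams(alpha_12=0.1, alpha_21=0.2, beta_12=np.log(1.25),
                        beta_21=0.0)
        hr = hazard_ratios(p, se_beta_12=0.1, se_beta_21=0.1)
        free = hr[~hr["fixed"]].set_index("transition")
        assert free.loc["1->2", "hr"] == pytest.approx(1.25, abs=1e-12)
        assert free.loc["2->1", "hr"] == pytest.approx(1.0)
        assert (hr[hr["fixed"]]["hr"] == 1.0).all()
        assert free.loc["1->2", "ci_low"] < 1.25 < free.loc["1->2", "ci_high"]


class TestForward:
    def test_identical_emissions_reduce_to_iid(self):
        rng = np.random.default_rng(3)
        p = _random_cthmm(rng)
        for arr in (p.r, p.p, p.pi):
            arr[1] = arr[0]
        series = _random_series(rng, 5)
        ll = forward_loglik(p, [series])
        iid = sum(zinb_logpmf(int(series[1][k, j]), p.r[0, j], p.p[0, j], p.pi[0, j])
                  for k in range(5) for j in range(4))
        assert ll == pytest.approx(iid, abs=1e-10)
        # changing Q must not matter
        p2 = CthmmParams(alpha_12=2.0, alpha_21=0.05, beta_12=1.0, beta_21=-1.0,
                         r=p.r, p=p.p, pi=p.pi, rho0=p.rho0)
        assert forward_loglik(p2, [series]) == pytest.approx(ll, abs=1e-10)

    @pytest.mark.parametrize("T", [1, 3, 6, 8])
    def test_equals_path_enumeration(self, T):
        rng = np.random.default_rng(40 + T)
        p = _random_cthmm(rng)
        t, scores, zb, zc = _random_series(rng, T)
        if T >= 3:
            scores[1, 2] = np.nan
        from esmdyn.cthmm import _emission_logprobs
        logE = _emission_logprobs(p, scores)
        lps = []
        for path in itertools.product([0, 1], repeat=T):
            lp = np.log(p.rho0[path[0]]) + logE[0, path[0]]
            for k in range(1, T):
                P = transition_probability(
                    intensity_matrix(p, zb[k - 1], zc[k - 1]), t[k] - t[k - 1])
                lp += np.log(P[path[k - 1], path[k]]) + logE[k, path[k]]
            lps.append(lp)
        oracle = np.logaddexp.reduce(lps)
        ll = forward_loglik(p, [(t, scores, zb, zc)])
        assert ll == pytest.approx(oracle, rel=1e-10)

    def test_single_observation(self):
        rng = np.random.default_rng(6)
        p = _random_cthmm(rng)
        t, scores, zb, zc = _random_series(rng, 1)
        from esmdyn.cthmm import _emission_logprobs
        logE = _emission_logprobs(p, scores)
        expected = np.log(np.sum(p.rho0 * np.exp(logE[0])))
        assert forward_loglik(p, [(t, scores, zb, zc)]) == \
            pytest.approx(expected, abs=1e-10)

    def test_batched_equals_reference(self):
        rng = np.random.default_rng(8)
        p = _random_cthmm(rng)
        subs = []
        for _ in range(5):
            T = int(rng.integers(1, 9))
            t, sc, zb, zc = _random_series(rng, T)
            sc[rng.random((T, 4)) < 0.15] = np.nan
            subs.append((t, sc, zb, zc))
        m = CthmmModel(subs)
        assert m.loglike(p) == pytest.approx(forward_loglik(p, subs), abs=1e-9)


class TestDecoding:
    def test_impossible_state_never_chosen(self):
        # state 2 cannot produce nonzero counts (pi ~ 1)
        p = CthmmParams(alpha_12=0.5, alpha_21=0.5,
                        r=np.full((2, 4), 2.0), p=np.full((2, 4), 0.5),
                        pi=np.array([[0.0] * 4, [1 - 1e-12] * 4]))
        rng = np.random.default_rng(9)
        t = np.arange(6) * 0.3
        scores = rng.integers(1, 6, (6, 4)).astype(float)
        path, gamma = viterbi_decode(p, (t, scores, None, None))
        assert (path == 0).all()
        assert np.allclose(gamma[:, 0], 1, atol=1e-9)

    @pytest.mark.parametrize("T", [2, 5, 8])
    def test_viterbi_matches_enumeration(self, T):
        rng = np.random.default_rng(50 + T)
        p = _random_cthmm(rng)
        t, scores, zb, zc = _random_series(rng, T)
        from esmdyn.cthmm import _emission_logprobs
        logE = _emission_logprobs(p, scores)
        best_lp, best_path = -np.inf, None
        for path in itertools.product([0, 1], repeat=T):
            lp = np.log(p.rho0[path[0]]) + logE[0, path[0]]
            for k in range(1, T):
                P = transition_probability(
                    intensity_matrix(p, zb[k - 1], zc[k - 1]), t[k] - t[k - 1])
                lp += np.log(P[path[k - 1], path[k]]) + logE[k, path[k]]
            if lp > best_lp:
                best_lp, best_path = lp, path
        vit, gamma = viterbi_decode(p, (t, scores, zb, zc))
        assert tuple(vit) == best_path
        assert np.allclose(gamma.sum(axis=1), 1, atol=1e-12)

    def test_smoothing_rows_sum_to_one(self):
        rng = np.random.default_rng(10)
        p = _random_cthmm(rng)
        gamma = forward_backward(p, _random_series(rng, 12))
        assert np.allclose(gamma.sum(axis=1), 1, atol=1e-12)


class TestProfilesAndFit:
    def test_profile_mean_and_zero_mass(self):
        p = CthmmParams(alpha_12=0.1, alpha_21=0.1,
                        r=np.full((2, 4), 2.0), p=np.full((2, 4), 0.5),
                        pi=np.zeros((2, 4)))
        prof = state_profiles(p)
        assert np.allclose(prof["mean"], 2.0)
        assert np.allclose(prof["p_zero"], 0.25)

    def test_relabeling_symmetry_of_loglik(self):
        """Swapping the state labels of the parameters leaves loglik unchanged."""
        rng = np.random.default_rng(12)
        p = _random_cthmm(rng)
        swapped = CthmmParams(
            alpha_12=p.alpha_21, alpha_21=p.alpha_12,
            beta_12=p.beta_21, beta_21=p.beta_12,
            r=p.r[::-1].copy(), p=p.p[::-1].copy(), pi=p.pi[::-1].copy(),
            rho0=p.rho0[::-1].copy())
        subs = [_random_series(rng, 6) for _ in range(3)]
        # swapped model with swapped covariate roles is the mirrored chain
        subs_swapped = [(t, sc, zc, zb) for t, sc, zb, zc in subs]
        assert forward_loglik(p, subs) == \
            pytest.approx(forward_loglik(swapped, subs_swapped), abs=1e-9)
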
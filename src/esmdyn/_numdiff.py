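"""Finite-difference derivatives for Wald standard errors and delta-method maps."""

from __future__ import annotations

import numpy as np


def approx_hessian(fun, x, step: float = 1e-4):
    """Central-difference Hessian of a scalar function at ``x``.

    Step sizes scale with the magnitude of each coordinate.  Symmetrized.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    h = step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h[i] ** 2
            else:
                fpp = fun(x + ei + ej)
                fpm = fun(x + ei - ej)
                fmp = fun(x - ei + ej)
                fmm = fun(x - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def approx_jacobian(fun, x, step: float = 1e-6):
    """Central-difference Jacobian of a vector function at ``x``."""
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(fun(x), dtype=float)
    J = np.empty((f0.size, x.size))
    for i in range(x.size):
        h = step * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        J[:, i] = (np.asarray(fun(xp)) - np.asarray(fun(xm))) / (2.0 * h)
    return J


def wald_cov(neg_loglik, x, step: float = 1e-4):
    """Inverse observed-information covariance; pseudo-inverse if singular."""
    H = approx_hessian(neg_loglik, x, step=step)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return cov
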
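"""Ornstein-Uhlenbeck densities, marginal moments, and bridge expectations.

The process for one gene is dX = -alpha (X - theta) dt + sigma dW. Its
transition kernel over an interval t is Gaussian,

    X_t | X_0 ~ N( e^{-alpha t} X_0 + (1 - e^{-alpha t}) theta,
                   sigma^2 (1 - e^{-2 alpha t}) / (2 alpha) ),

and with a Gaussian initial state S ~ N(mu0, var0) the marginal of the
observation at time t is again Gaussian with moments given by
:func:`ou_marginal_moments`. Every quantity here is closed form; the
discretized-path routines exist as exact finite-N oracles for the
continuous-time bridge expectations, not as production code paths.

All `1 - e^{-x}` style terms are computed through ``numpy.expm1`` so that
small alpha*t never suffers catastrophic cancellation.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .types import InitialDistribution, OUGeneParams, ParameterError, VAR_FLOOR

_LOG_2PI = float(np.log(2.0 * np.pi))

__all__ = [
    "ou_transition_moments",
    "ou_transition_logpdf",
    "ou_marginal_moments",
    "ou_marginal_logpdf",
    "cell_loglik",
    "posterior_initial_moments",
    "ou_bridge_mean",
    "discrete_path_conditional",
    "bridge_sufficient_stats",
]


def _check_params(alpha, sigma2):
    alpha = np.asarray(alpha, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(alpha <= 0):
        raise ParameterError("alpha must be strictly positive")
    if np.any(sigma2 <= 0):
        raise ParameterError("sigma2 must be strictly positive")
    return alpha, sigma2


def _gene_params(p: OUGeneParams, k: int):
    """Scalar (alpha, sigma2, theta_k) from a single-gene parameter set."""
    if p.n_genes != 1:
        raise ParameterError("expected single-gene parameters")
    return float(p.alpha[0]), float(p.sigma2[0]), float(p.theta[0, k])


def ou_transition_moments(x0, alpha, sigma2, theta, t):
    """Mean and variance of X_t given X_0 = x0. Broadcasts over inputs."""
    alpha, sigma2 = _check_params(alpha, sigma2)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("elapsed time must be non-negative")
    decay = np.exp(-alpha * t)
    mean = decay * np.asarray(x0, dtype=float) + (-np.expm1(-alpha * t)) * theta
    var = sigma2 * (-np.expm1(-2.0 * alpha * t)) / (2.0 * alpha)
    return mean, var


def _normal_logpdf(x, mean, var):
    var = np.maximum(var, VAR_FLOOR)
    return -0.5 * (_LOG_2PI + np.log(var)) - 0.5 * (x - mean) ** 2 / var


def ou_transition_logpdf(x, x0, p: OUGeneParams, t, k: int = 0):
    """Log transition density log P(X_t = x | X_0 = x0).

    The t = 0 kernel is a point mass at x0 and has no density; calling with
    t = 0 raises rather than silently returning NaN.
    """
    alpha, sigma2, theta = _gene_params(p, k)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ParameterError("transition density is degenerate at t = 0; need t > 0")
    mean, var = ou_transition_moments(x0, alpha, sigma2, theta, t)
    return _normal_logpdf(np.asarray(x, dtype=float), mean, var)


def ou_marginal_moments(p: OUGeneParams, init: InitialDistribution, t, k: int = 0, g: int = 0):
    """Moments of the observation at time t with S ~ N(mu0, var0) integrated out.

        mu_t  = e^{-alpha t} mu0 + (1 - e^{-alpha t}) theta
        var_t = sigma^2 (1 - e^{-2 alpha t}) / (2 alpha) + e^{-2 alpha t} var0
    """
    alpha, sigma2, theta = _gene_params(p, k)
    mu0, var0 = float(init.mu0[g]), float(init.var0[g])
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("t must be non-negative")
    mean, trans_var = ou_transition_moments(mu0, alpha, sigma2, theta, t)
    var = trans_var + np.exp(-2.0 * alpha * t) * var0
    return mean, var


def marginal_moments_matrix(t, alpha, sigma2, theta, mu0, var0):
    """Vectorized marginal moments for all cells x genes (x lineages).

    Parameters are gene-indexed arrays; ``theta`` may be (G,) or (G, K).
    Returns ``mean`` with shape (C, G) or (C, G, K) and ``var`` with shape
    (C, G) (the variance does not depend on the lineage attractor).
    """
    t = np.asarray(t, dtype=float)[:, None]
    decay = np.exp(-t * alpha)  # (C, G)
    grow = -np.expm1(-t * alpha)
    var = sigma2 * (-np.expm1(-2.0 * t * alpha)) / (2.0 * alpha) + decay**2 * var0
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 1:
        mean = decay * mu0 + grow * theta
    else:
        mean = decay[:, :, None] * mu0[None, :, None] + grow[:, :, None] * theta[None, :, :]
    return mean, np.maximum(var, VAR_FLOOR)


def ou_marginal_logpdf(e, p: OUGeneParams, init: InitialDistribution, t, k: int = 0, g: int = 0):
    """Log marginal density of an observation: Gaussian with marginal moments."""
    mean, var = ou_marginal_moments(p, init, t, k=k, g=g)
    if np.any(var <= 0):
        raise ParameterError("marginal variance is non-positive")
    return _normal_logpdf(np.asarray(e, dtype=float), mean, var)


def cell_loglik(e_row, params: OUGeneParams, init: InitialDistribution, t, k: int = 0):
    """Log-likelihood of one cell under lineage k: sum over independent genes."""
    e_row = np.asarray(e_row, dtype=float)
    if e_row.shape != (params.n_genes,) or init.n_genes != params.n_genes:
        raise ParameterError("gene counts of expression row, params and init must agree")
    mean, var = marginal_moments_matrix(
        np.atleast_1d(float(t)), params.alpha, params.sigma2,
        params.theta[:, k], init.mu0, init.var0,
    )
    return float(_normal_logpdf(e_row, mean[0], var[0]).sum())


def posterior_initial_moments(e, p: OUGeneParams, init: InitialDistribution, t,
                              k: int = 0, g: int = 0):
    """Gaussian posterior of the initial state S given the observation e.

    (S, E) is jointly Gaussian with Cov(S, E) = e^{-alpha t} var0, so the
    posterior follows by linear conditioning. At t = 0 the observation IS the
    initial state and (e, 0) is returned.
    """
    alpha, sigma2, theta = _gene_params(p, k)
    mu0, var0 = float(init.mu0[g]), float(init.var0[g])
    t = float(t)
    if t < 0:
        raise ParameterError("t must be non-negative")
    if t == 0.0:
        return float(e), 0.0
    decay = np.exp(-alpha * t)
    obs_mean = decay * mu0 + (-np.expm1(-alpha * t)) * theta
    trans_var = sigma2 * (-np.expm1(-2.0 * alpha * t)) / (2.0 * alpha)
    obs_var = decay**2 * var0 + trans_var
    gain = decay * var0 / obs_var
    post_mean = mu0 + gain * (float(e) - obs_mean)
    post_var = var0 - gain * decay * var0
    return float(post_mean), float(max(post_var, 0.0))


def _sinh_ratio(a, b):
    """sinh(a)/sinh(b) for 0 <= a <= b, computed without overflow."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    # sinh(a)/sinh(b) = e^{a-b} (1 - e^{-2a}) / (1 - e^{-2b})
    return np.exp(a - b) * np.expm1(-2.0 * a) / np.expm1(-2.0 * b)


def ou_bridge_mean(x0, xN, p: OUGeneParams, t, s, k: int = 0):
    """Expected value of the OU path at interior time s given both endpoints.

        E[X_s | X_0 = x0, X_t = xN]
          = theta + [ (x0 - theta) sinh(alpha (t - s)) + (xN - theta) sinh(alpha s) ]
                    / sinh(alpha t)
    """
    alpha, _, theta = _gene_params(p, k)
    t = float(t)
    s = np.asarray(s, dtype=float)
    if t <= 0:
        raise ParameterError("bridge requires t > 0")
    if np.any(s < 0) or np.any(s > t):
        raise ParameterError("interior time must satisfy 0 <= s <= t")
    w0 = _sinh_ratio(alpha * (t - s), alpha * t)
    wN = _sinh_ratio(alpha * s, alpha * t)
    return theta + (x0 - theta) * w0 + (xN - theta) * wN


_MAX_ORACLE_N = 5000


def discrete_path_conditional(x0, xN, p: OUGeneParams, t, N: int, k: int = 0):
    """Exact conditional law of the discretized OU path interior points.

    The chain X_0..X_N with step t/N has Gaussian transitions; conditioning
    the interior X_1..X_{N-1} on both endpoints gives a multivariate normal
    whose precision is tridiagonal. Returns (mean, covariance) of the
    interior points. Intended as a finite-N oracle (N is capped) for the
    closed-form bridge expectations.
    """
    alpha, sigma2, theta = _gene_params(p, k)
    t = float(t)
    if t <= 0:
        raise ParameterError("need t > 0")
    if N < 2:
        raise ParameterError("need N >= 2")
    if N > _MAX_ORACLE_N:
        raise ParameterError(f"oracle guard: N must be <= {_MAX_ORACLE_N}")
    dt = t / N
    a = float(np.exp(-alpha * dt))
    v = float(sigma2 * (-np.expm1(-2.0 * alpha * dt)) / (2.0 * alpha))
    b0 = float(-np.expm1(-alpha * dt)) * theta
    n = N - 1
    # Tridiagonal precision: diag (1+a^2)/v, off-diagonal -a/v.
    h = np.full(n, b0 * (1.0 - a) / v)
    h[0] += a * float(x0) / v
    h[-1] += a * float(xN) / v
    if n == 1:
        prec_scalar = (1.0 + a * a) / v
        return h / prec_scalar, np.array([[1.0 / prec_scalar]])
    ab = np.empty((2, n))
    ab[0, :] = -a / v
    ab[0, 0] = 0.0  # unused superdiagonal slot
    ab[1, :] = (1.0 + a * a) / v
    mean = scipy.linalg.solveh_banded(ab, h, lower=False)
    prec = np.zeros((n, n))
    idx = np.arange(n)
    prec[idx, idx] = (1.0 + a * a) / v
    prec[idx[:-1], idx[:-1] + 1] = -a / v
    prec[idx[:-1] + 1, idx[:-1]] = -a / v
    cov = scipy.linalg.inv(prec)
    cov = 0.5 * (cov + cov.T)
    return mean, cov


def bridge_sufficient_stats(x0, xN, p: OUGeneParams, t, N: int, k: int = 0):
    """Expected path statistics E[sum X_s^2], E[sum X_s X_{s+1}], E[sum X_s].

    Computed from the exact discrete-path conditional mean and covariance:
    the interior squared sum runs s = 1..N-1, the cross term s = 0..N-1
    (including both endpoint products), the plain sum s = 1..N-1.
    """
    mean, cov = discrete_path_conditional(x0, xN, p, t, N, k=k)
    d = np.diag(cov)
    sum_sq = float(np.sum(mean**2 + d))
    off = np.diag(cov, 1) if len(mean) > 1 else np.array([])
    cross = float(x0) * mean[0] + float(xN) * mean[-1]
    if len(mean) > 1:
        cross += float(np.sum(mean[:-1] * mean[1:] + off))
    sum_x = float(np.sum(mean))
    return sum_sq, float(cross), sum_x
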
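"""EM fitting of the single-lineage and mixture OU models.

The marginal likelihood of a cell under lineage k is a product over genes of
Gaussians whose moments come from the OU marginal (initial state integrated
out analytically). Fitting is coordinate ascent on that marginal likelihood:

* attractors theta_gk have a closed-form weighted maximizer,
* alpha_g and sigma2_g are updated by bounded 1-D maximization of the exact
  per-gene weighted marginal log-likelihood (coarse grid bracket followed by
  golden section), accepted only if they improve,
* lineage responsibilities gamma and weights pi follow the standard mixture
  E-step / M-step,
* each cell's pseudo-time t_c is updated by a bracketed search plus Newton
  polish with step halving, accepted only if it improves.

Every accepted step does not decrease the marginal log-likelihood, so the
per-iteration trace is non-decreasing (up to floating-point slack).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .model import marginal_moments_matrix
from .types import (
    CellLatentState,
    DataError,
    ExpressionMatrix,
    InitialDistribution,
    MixtureFit,
    OUGeneParams,
    ParameterError,
)

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class FitConfig:
    """Optimization settings for the EM fit."""

    max_iter: int = 100
    tol: float = 1e-6
    t_bounds: tuple[float, float] = (1e-6, 100.0)
    alpha_bounds: tuple[float, float] = (1e-4, 1e2)
    sigma2_min: float = 1e-6
    sigma2_max: float = 1e4
    newton_max_steps: int = 20
    seed: int = 0
    n_restarts: int = 3
    theta_margin: float = 0.25

    def __post_init__(self):
        if self.tol <= 0:
            raise ParameterError("tol must be positive")
        for lo, hi in (self.t_bounds, self.alpha_bounds, (self.sigma2_min, self.sigma2_max)):
            if not (0 < lo < hi):
                raise ParameterError("bounds must satisfy 0 < lower < upper")


# ---------------------------------------------------------------------------
# vectorized likelihood pieces


def _loglik_cgk(E, t, alpha, sigma2, theta, mu0, var0):
    """(C, G, K) per-cell per-gene per-lineage marginal log-density."""
    mean, var = marginal_moments_matrix(t, alpha, sigma2, theta, mu0, var0)
    base = -0.5 * (_LOG_2PI + np.log(var))
    return base[:, :, None] - 0.5 * (E[:, :, None] - mean) ** 2 / var[:, :, None]


def _cell_lineage_loglik(E, t, alpha, sigma2, theta, mu0, var0):
    """(C, K) log-likelihood of each cell under each lineage."""
    return _loglik_cgk(E, t, alpha, sigma2, theta, mu0, var0).sum(axis=1)


def _marginal_loglik(E, t, alpha, sigma2, theta, mu0, var0, pi):
    L = _cell_lineage_loglik(E, t, alpha, sigma2, theta, mu0, var0)
    with np.errstate(divide="ignore"):
        return float(logsumexp(L + np.log(pi)[None, :], axis=1).sum())


def _responsibilities_from_loglik(L, pi):
    with np.errstate(divide="ignore"):
        logw = L + np.log(pi)[None, :]
    logw -= logsumexp(logw, axis=1, keepdims=True)
    gamma = np.exp(logw)
    return gamma / gamma.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# coordinate updates


def _theta_closed_form(E, t, alpha, sigma2, gamma, mu0, var0, theta_old, bounds=None):
    """Exact maximizer of the gamma-weighted marginal log-likelihood in theta.

    theta*_gk = [sum_c gamma_ck (1-A) (E - A mu0) / V] / [sum_c gamma_ck (1-A)^2 / V]
    with A = e^{-alpha t_c} and V the marginal variance. When ``bounds`` is
    given the maximizer is clamped into [lo_g, hi_g] (the objective is
    concave in theta, so clamping yields the constrained maximizer).
    """
    t = np.asarray(t, dtype=float)[:, None]
    A = np.exp(-t * alpha)
    grow = -np.expm1(-t * alpha)
    V = sigma2 * (-np.expm1(-2.0 * t * alpha)) / (2.0 * alpha) + A**2 * var0
    V = np.maximum(V, 1e-12)
    resid = (E - A * mu0) * grow / V  # (C, G)
    wsq = grow**2 / V
    num = np.einsum("ck,cg->gk", gamma, resid)
    den = np.einsum("ck,cg->gk", gamma, wsq)
    theta = np.array(theta_old, dtype=float, copy=True)
    ok = den > 1e-12
    theta[ok] = (num / np.maximum(den, 1e-12))[ok]
    if bounds is not None:
        theta = np.clip(theta, bounds[0][:, None], bounds[1][:, None])
    return theta, ok


def _vector_golden_max(f, lo, hi, n_iter=28):
    """Per-component golden-section maximization of f over [lo, hi] arrays.

    ``f`` maps a parameter vector to a same-shaped objective vector; the
    search runs simultaneously on every component.
    """
    a = np.array(lo, dtype=float, copy=True)
    b = np.array(hi, dtype=float, copy=True)
    for _ in range(n_iter):
        span = b - a
        c = b - _INVPHI * span
        d = a + _INVPHI * span
        fc = f(c)
        fd = f(d)
        left = fc >= fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
    mid = 0.5 * (a + b)
    return mid, f(mid)


def _grid_bracket(f, lo, hi, n_grid, size):
    """Coarse log-spaced scan; returns per-component bracket around the argmax."""
    grid = np.geomspace(lo, hi, n_grid)
    vals = np.empty((n_grid, size))
    for i, gval in enumerate(grid):
        vals[i] = f(np.full(size, gval))
    best = np.argmax(vals, axis=0)
    lo_idx = np.maximum(best - 1, 0)
    hi_idx = np.minimum(best + 1, n_grid - 1)
    return grid[lo_idx], grid[hi_idx]


def _profile_theta(E, t_col, alpha_vec, sigma2, gamma, mu0, var0, theta_old, bounds=None):
    """Closed-form theta*(alpha) for every gene/lineage at candidate alphas."""
    A = np.exp(-t_col * alpha_vec)
    grow = -np.expm1(-t_col * alpha_vec)
    V = sigma2 * (-np.expm1(-2.0 * t_col * alpha_vec)) / (2.0 * alpha_vec) + A**2 * var0
    V = np.maximum(V, 1e-12)
    resid = (E - A * mu0) * grow / V
    wsq = grow**2 / V
    num = np.einsum("ck,cg->gk", gamma, resid)
    den = np.einsum("ck,cg->gk", gamma, wsq)
    theta = np.where(den > 1e-12, num / np.maximum(den, 1e-12), theta_old)
    if bounds is not None:
        theta = np.clip(theta, bounds[0][:, None], bounds[1][:, None])
    return theta, A, grow, V


def _update_alpha_sigma2(E, t, alpha, sigma2, theta, gamma, mu0, var0, cfg: FitConfig,
                         bounds=None):
    """Joint (alpha, theta-profiled) update then sigma2, accept-if-improved per gene.

    theta is profiled out in closed form inside the alpha search: alpha and
    theta trade off along a ridge (alpha -> 0 with theta -> inf fits the same
    early-time trend), and coordinate-wise moves stall on that ridge while
    the profile search follows it. With attractor ``bounds`` the profile is
    the constrained maximizer, which cuts the degenerate end of the ridge.
    """
    t_col = np.asarray(t, dtype=float)[:, None]
    G = E.shape[1]

    def obj_alpha(alpha_vec):
        th, A, grow, V = _profile_theta(E, t_col, alpha_vec, sigma2, gamma, mu0,
                                        var0, theta, bounds)
        mean = A[:, :, None] * mu0[None, :, None] + grow[:, :, None] * th[None, :, :]
        ll = (-0.5 * (_LOG_2PI + np.log(V)))[:, :, None] \
            - 0.5 * (E[:, :, None] - mean) ** 2 / V[:, :, None]
        return np.einsum("ck,cgk->g", gamma, ll)

    def obj_at(alpha_vec, theta_mat):
        ll = _loglik_cgk(E, t, alpha_vec, sigma2, theta_mat, mu0, var0)
        return np.einsum("ck,cgk->g", gamma, ll)

    base = obj_at(alpha, theta)
    lo, hi = _grid_bracket(obj_alpha, cfg.alpha_bounds[0], cfg.alpha_bounds[1], 24, G)
    # golden section in log space
    cand, cand_val = _vector_golden_max(
        lambda u: obj_alpha(np.exp(u)), np.log(lo), np.log(hi)
    )
    cand = np.exp(cand)
    theta_cand, _, _, _ = _profile_theta(E, t_col, cand, sigma2, gamma, mu0, var0,
                                         theta, bounds)
    improved_a = cand_val > base
    alpha_new = np.where(improved_a, cand, alpha)
    theta = np.where(improved_a[:, None], theta_cand, theta)

    # sigma2: the mean and the alpha-dependent pieces are fixed, so cache them
    A = np.exp(-t_col * alpha_new)
    grow = -np.expm1(-t_col * alpha_new)
    B = (-np.expm1(-2.0 * t_col * alpha_new)) / (2.0 * alpha_new)
    mean = A[:, :, None] * mu0[None, :, None] + grow[:, :, None] * theta[None, :, :]
    sq = np.einsum("ck,cgk->cg", gamma, (E[:, :, None] - mean) ** 2)
    wsum = gamma.sum(axis=1)  # per-cell total weight (1 for proper gamma rows)

    def obj_sigma2(s2_vec):
        V = np.maximum(s2_vec * B + A**2 * var0, 1e-12)
        return (
            -0.5 * ((_LOG_2PI + np.log(V)) * wsum[:, None]).sum(axis=0)
            - 0.5 * (sq / V).sum(axis=0)
        )

    base2 = obj_sigma2(sigma2)
    lo2, hi2 = _grid_bracket(obj_sigma2, cfg.sigma2_min, cfg.sigma2_max, 16, G)
    cand2, cand2_val = _vector_golden_max(
        lambda u: obj_sigma2(np.exp(u)), np.log(lo2), np.log(hi2)
    )
    sigma2_new = np.where(cand2_val > base2, np.exp(cand2), sigma2)
    improved = improved_a | (cand2_val > base2)
    return alpha_new, sigma2_new, theta, improved


def _update_pseudotimes(E, t, alpha, sigma2, theta, gamma, mu0, var0, cfg: FitConfig,
                        n_grid=48):
    """Per-cell pseudo-time update: grid bracket + golden section + Newton polish."""
    t_lo, t_hi = cfg.t_bounds
    C = E.shape[0]

    def obj(t_vec):
        ll = _loglik_cgk(E, t_vec, alpha, sigma2, theta, mu0, var0)
        return np.einsum("ck,cgk->c", gamma, ll)

    base = obj(t)
    grid = np.geomspace(t_lo, t_hi, n_grid)
    vals = np.empty((n_grid, C))
    for i, gval in enumerate(grid):
        vals[i] = obj(np.full(C, gval))
    best = np.argmax(vals, axis=0)  # first (smallest-t) argmax on ties
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, n_grid - 1)]
    cand, cand_val = _vector_golden_max(lambda u: obj(np.exp(u)), np.log(lo), np.log(hi),
                                        n_iter=36)
    cand = np.exp(cand)

    t_new = np.where(cand_val > base, cand, t)
    f_new = np.maximum(cand_val, base)

    # Newton polish with step halving (finite-difference derivatives)
    for _ in range(min(cfg.newton_max_steps, 8)):
        h = 1e-5 * np.maximum(t_new, 1e-2)
        f_plus = obj(np.clip(t_new + h, t_lo, t_hi))
        f_minus = obj(np.clip(t_new - h, t_lo, t_hi))
        grad = (f_plus - f_minus) / (2.0 * h)
        hess = (f_plus - 2.0 * f_new + f_minus) / h**2
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(hess < 0, -grad / hess, np.sign(grad) * h)
        step = np.where(np.isfinite(step), step, 0.0)
        moved = False
        for _halve in range(4):
            trial = np.clip(t_new + step, t_lo, t_hi)
            f_trial = obj(trial)
            accept = f_trial > f_new
            if np.any(accept):
                t_new = np.where(accept, trial, t_new)
                f_new = np.where(accept, f_trial, f_new)
                moved = True
            step = 0.5 * step
        if not moved:
            break
    # tie-break toward smaller t when the move did not strictly improve
    t_new = np.where(f_new > base, t_new, np.minimum(t_new, t))
    return t_new


# ---------------------------------------------------------------------------
# public single-step operations (spec surface)


def update_theta_gene(e_col, init: InitialDistribution, alpha: float, sigma2: float,
                      t_vec, weights, g: int = 0) -> float:
    """Closed-form attractor update for one gene under cell weights."""
    e_col = np.asarray(e_col, dtype=float)
    t_vec = np.asarray(t_vec, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.all(w * t_vec < 1e-12):
        raise ParameterError("attractor undefined: no cell with positive weight and time")
    theta, ok = _theta_closed_form(
        e_col[:, None], t_vec, np.array([alpha]), np.array([sigma2]),
        w[:, None], np.array([init.mu0[g]]), np.array([init.var0[g]]),
        np.zeros((1, 1)),
    )
    if not ok[0, 0]:
        raise ParameterError("attractor undefined: degenerate weights/times")
    return float(theta[0, 0])


def update_alpha_sigma2_gene(e_col, init: InitialDistribution, thetas, t_vec, weights,
                             cfg: FitConfig, alpha: float = 1.0, sigma2: float = 1.0,
                             g: int = 0):
    """Numeric (alpha, sigma2) update for one gene; never decreases the objective."""
    e_col = np.asarray(e_col, dtype=float)[:, None]
    t_vec = np.asarray(t_vec, dtype=float)
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    w = np.asarray(weights, dtype=float)
    gamma = w[:, None] if w.ndim == 1 else w
    if gamma.shape[1] != len(thetas):
        raise DataError("weights columns must match the number of attractors")
    th = np.asarray(thetas, dtype=float)[None, :]
    mu0_g, var0_g = np.array([init.mu0[g]]), np.array([init.var0[g]])
    a_new, s2_new, _, _ = _update_alpha_sigma2(
        e_col, t_vec, np.array([alpha]), np.array([sigma2]), th, gamma,
        mu0_g, var0_g, cfg,
    )

    def obj(a, s2):
        ll = _loglik_cgk(e_col, t_vec, np.array([a]), np.array([s2]), th, mu0_g, var0_g)
        return float(np.einsum("ck,cgk->g", gamma, ll)[0])

    # attractors are fixed in this operation: keep the candidate only if it
    # improves the fixed-theta objective
    if obj(float(a_new[0]), float(s2_new[0])) >= obj(alpha, sigma2):
        return float(a_new[0]), float(s2_new[0])
    return float(alpha), float(sigma2)


def update_pseudotime_cell(e_row, params: OUGeneParams, init: InitialDistribution,
                           pi, gamma_row, t_prev: float, cfg: FitConfig) -> float:
    """Pseudo-time update for a single cell given its responsibilities."""
    e_row = np.asarray(e_row, dtype=float)[None, :]
    gamma_row = np.asarray(gamma_row, dtype=float)[None, :]
    t_new = _update_pseudotimes(
        e_row, np.array([float(t_prev)]), params.alpha, params.sigma2, params.theta,
        gamma_row, init.mu0, init.var0, cfg,
    )
    return float(t_new[0])


def responsibilities(E: ExpressionMatrix, fit: MixtureFit) -> np.ndarray:
    """Posterior lineage probabilities gamma_ck for every cell (rows sum to 1)."""
    L = _cell_lineage_loglik(
        E.values, fit.cells.t, fit.params.alpha, fit.params.sigma2,
        fit.params.theta, fit.init.mu0, fit.init.var0,
    )
    return _responsibilities_from_loglik(L, fit.pi)


def update_mixture_weights(gamma) -> np.ndarray:
    """Mixture weights pi_k = sum_c gamma_ck / sum_ck gamma_ck."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.size == 0:
        raise DataError("empty responsibility matrix")
    total = gamma.sum()
    return gamma.sum(axis=0) / total


def assign_lineage(gamma, threshold: float = 0.5) -> list:
    """Hard lineage call per cell: 0-based index k iff gamma_ck > threshold,
    otherwise the string "uncertain"."""
    if not (0 < threshold < 1):
        raise ParameterError("threshold must lie in (0, 1)")
    gamma = np.asarray(gamma, dtype=float)
    out = []
    for row in gamma:
        k = int(np.argmax(row))
        out.append(k if row[k] > threshold else "uncertain")
    return out


# ---------------------------------------------------------------------------
# full fits


def _initial_params(E, t_init, K, cfg: FitConfig, init: InitialDistribution, seed: int):
    C, G = E.shape
    alpha = np.ones(G)
    sigma2 = np.clip(E.var(axis=0), cfg.sigma2_min, cfg.sigma2_max)
    if K == 1:
        theta, _ = _theta_closed_form(
            E, t_init, alpha, sigma2, np.ones((C, 1)), init.mu0, init.var0,
            E.mean(axis=0)[:, None],
        )
    else:
        # late (top-quartile pseudo-time) cells carry the lineage signal
        cutoff = np.quantile(t_init, 0.75)
        late = t_init >= cutoff
        if late.sum() < K:
            late = np.argsort(t_init)[-max(K, C // 4):]
        X_late = E[late]
        km = KMeans(n_clusters=K, n_init=10, random_state=seed % (2**31)).fit(X_late)
        theta = np.vstack([
            X_late[km.labels_ == k].mean(axis=0) if np.any(km.labels_ == k)
            else E.mean(axis=0)
            for k in range(K)
        ]).T
    pi = np.full(K, 1.0 / K)
    return alpha, sigma2, theta, pi


def _fit_once(E, init: InitialDistribution, K, t_init, cfg: FitConfig, seed: int):
    C, G = E.shape
    mu0, var0 = init.mu0, init.var0
    t = np.clip(np.asarray(t_init, dtype=float), cfg.t_bounds[0], cfg.t_bounds[1])
    alpha, sigma2, theta, pi = _initial_params(E, t, K, cfg, init, seed)
    # attractor identifiability constraint: theta within the observed per-gene
    # expression range widened by theta_margin range-widths on each side
    span = E.max(axis=0) - E.min(axis=0)
    bounds = (E.min(axis=0) - cfg.theta_margin * span,
              E.max(axis=0) + cfg.theta_margin * span)
    theta = np.clip(theta, bounds[0][:, None], bounds[1][:, None])
    L = _cell_lineage_loglik(E, t, alpha, sigma2, theta, mu0, var0)
    gamma = _responsibilities_from_loglik(L, pi)
    trace = []
    collapsed = False
    for _ in range(cfg.max_iter):
        theta, _ = _theta_closed_form(E, t, alpha, sigma2, gamma, mu0, var0, theta,
                                      bounds)
        alpha, sigma2, theta, _ = _update_alpha_sigma2(E, t, alpha, sigma2, theta,
                                                       gamma, mu0, var0, cfg, bounds)
        L = _cell_lineage_loglik(E, t, alpha, sigma2, theta, mu0, var0)
        gamma = _responsibilities_from_loglik(L, pi)
        pi = update_mixture_weights(gamma)
        if K > 1 and np.any(gamma.sum(axis=0) < 1e-3):
            collapsed = True
            break
        t = _update_pseudotimes(E, t, alpha, sigma2, theta, gamma, mu0, var0, cfg)
        ll = _marginal_loglik(E, t, alpha, sigma2, theta, mu0, var0, pi)
        logger.info("EM iteration %d: marginal log-likelihood %.6f", len(trace) + 1, ll)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < cfg.tol * max(1.0, abs(trace[-1])):
            break
    # final E-step so gamma/pi are consistent with the returned parameters
    L = _cell_lineage_loglik(E, t, alpha, sigma2, theta, mu0, var0)
    gamma = _responsibilities_from_loglik(L, pi)
    if not trace:
        trace.append(_marginal_loglik(E, t, alpha, sigma2, theta, mu0, var0, pi))
    return dict(alpha=alpha, sigma2=sigma2, theta=theta, pi=pi, t=t, gamma=gamma,
                trace=np.asarray(trace), collapsed=collapsed)


def fit_mixture(E: ExpressionMatrix, init: InitialDistribution, K: int, t_init,
                cfg: FitConfig | None = None) -> MixtureFit:
    """Fit the K-lineage mixture OU model by coordinate-ascent EM.

    ``t_init`` seeds the per-cell pseudo-times (typically from
    :func:`oudiff.pseudotime.sp_pseudotime`). For K >= 2 the best of
    ``cfg.n_restarts`` differently-seeded attractor initializations is kept;
    K = 1 is deterministic and runs once.
    """
    cfg = cfg or FitConfig()
    if K < 1:
        raise ParameterError("K must be >= 1")
    Ev = E.values
    if init.n_genes != E.n_genes:
        raise DataError("initial distribution gene count does not match expression")
    t_init = np.asarray(t_init, dtype=float)
    if t_init.shape != (E.n_cells,):
        raise DataError("t_init must have one entry per cell")
    if not np.all(np.isfinite(t_init)):
        raise DataError("t_init contains non-finite values")

    n_runs = 1 if K == 1 else max(1, cfg.n_restarts)
    results = []
    seed = cfg.seed
    attempts = 0
    while len(results) < n_runs and attempts < 3 * n_runs:
        res = _fit_once(Ev, init, K, t_init, cfg, seed=seed + attempts)
        attempts += 1
        if res["collapsed"]:
            warnings.warn("a lineage collapsed during EM; restarting with a new seed")
            logger.warning("lineage collapse at seed %d; restarting", seed + attempts - 1)
            continue
        results.append(res)
    if not results:  # every restart collapsed; keep the last attempt regardless
        results.append(res)
    best = max(results, key=lambda r: r["trace"][-1])
    return MixtureFit(
        K=K, pi=best["pi"],
        params=OUGeneParams(alpha=best["alpha"], sigma2=best["sigma2"], theta=best["theta"]),
        cells=CellLatentState(t=best["t"], gamma=best["gamma"]),
        init=init, loglik_trace=best["trace"],
        gene_ids=E.gene_ids, cell_ids=E.cell_ids,
    )


def fit_single_lineage(E: ExpressionMatrix, init: InitialDistribution, t_init,
                       cfg: FitConfig | None = None) -> MixtureFit:
    """Fit the single-lineage model (exactly the K = 1 mixture path)."""
    return fit_mixture(E, init, 1, t_init, cfg)


def marginal_loglik(E: ExpressionMatrix, fit: MixtureFit) -> float:
    """Total marginal log-likelihood of the data under a fit."""
    return _marginal_loglik(
        E.values, fit.cells.t, fit.params.alpha, fit.params.sigma2,
        fit.params.theta, fit.init.mu0, fit.init.var0, fit.pi,
    )
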
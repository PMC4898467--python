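"""Tests of the EM machinery: coordinate updates, responsibilities, full fits."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from oudiff.inference import (
    FitConfig,
    assign_lineage,
    fit_mixture,
    fit_single_lineage,
    responsibilities,
    update_alpha_sigma2_gene,
    update_mixture_weights,
    update_pseudotime_cell,
    update_theta_gene,
    _cell_lineage_loglik,
    _loglik_cgk,
)
from oudiff.pseudotime import sp_pseudotime
from oudiff.simulate import SimulationSpec, simulate_dataset
from oudiff.types import (
    CellLatentState,
    InitialDistribution,
    MixtureFit,
    OUGeneParams,
    ParameterError,
)


def _gene_obj(e_col, t_vec, w, alpha, sigma2, theta, mu0, var0):
    ll = _loglik_cgk(np.asarray(e_col, float)[:, None], np.asarray(t_vec, float),
                     np.array([alpha]), np.array([sigma2]),
                     np.array([[theta]]), np.array([mu0]), np.array([var0]))
    return float((np.asarray(w, float) * ll[:, 0, 0]).sum())


class TestThetaUpdate:
    def test_stationary_regime_weighted_mean(self):
        init = InitialDistribution(mu0=[0.0], var0=[0.3])
        e = np.array([2.0, 4.0, 3.0])
        t = np.full(3, 50.0)
        w = np.array([1.0, 1.0, 2.0])
        theta = update_theta_gene(e, init, 1.0, 1.0, t, w)
        assert theta == pytest.approx(np.average(e, weights=w), abs=1e-6)

    def test_single_cell_interpolation(self):
        # sigma0^2 ~ 0: theta solves e = a mu0 + (1-a) theta exactly
        init = InitialDistribution(mu0=[1.0], var0=[0.0], var_floor=1e-300)
        alpha, t, e = 0.8, 0.9, 2.7
        theta = update_theta_gene(np.array([e]), init, alpha, 1.0, np.array([t]),
                                  np.array([1.0]))
        a = np.exp(-alpha * t)
        assert a * 1.0 + (1 - a) * theta == pytest.approx(e, abs=1e-9)

    def test_matches_numeric_maximizer(self):
        rng = np.random.default_rng(3)
        init = InitialDistribution(mu0=[0.5], var0=[0.4])
        e = rng.normal(1.0, 1.0, size=20)
        t = rng.uniform(0.1, 2.0, size=20)
        w = rng.uniform(0.2, 1.0, size=20)
        theta = update_theta_gene(e, init, 1.2, 0.9, t, w)
        res = minimize_scalar(
            lambda th: -_gene_obj(e, t, w, 1.2, 0.9, th, 0.5, 0.4),
            bounds=(-20, 20), method="bounded",
            options={"xatol": 1e-10})
        assert theta == pytest.approx(res.x, abs=1e-6)
        # stationarity: central-difference gradient near zero
        h = 1e-5
        grad = (_gene_obj(e, t, w, 1.2, 0.9, theta + h, 0.5, 0.4)
                - _gene_obj(e, t, w, 1.2, 0.9, theta - h, 0.5, 0.4)) / (2 * h)
        assert abs(grad) < 1e-6

    def test_degenerate_weights_error(self):
        init = InitialDistribution(mu0=[0.0], var0=[0.3])
        with pytest.raises(ParameterError):
            update_theta_gene(np.array([1.0, 2.0]), init, 1.0, 1.0,
                              np.zeros(2), np.ones(2))


class TestAlphaSigma2Update:
    def test_monotonicity_contract(self):
        rng = np.random.default_rng(5)
        init = InitialDistribution(mu0=[0.0], var0=[0.3])
        cfg = FitConfig()
        e = rng.normal(2.0, 1.0, size=40)
        t = rng.uniform(0.1, 2.0, size=40)
        w = np.ones(40)
        before = _gene_obj(e, t, w, 0.4, 2.5, 2.0, 0.0, 0.3)
        a, s2 = update_alpha_sigma2_gene(e, init, [2.0], t, w, cfg,
                                         alpha=0.4, sigma2=2.5)
        after = _gene_obj(e, t, w, a, s2, 2.0, 0.0, 0.3)
        assert after >= before - 1e-9
        assert cfg.alpha_bounds[0] <= a <= cfg.alpha_bounds[1]

    def test_zero_residual_drives_sigma2_to_floor(self):
        init = InitialDistribution(mu0=[2.0], var0=[1e-6])
        cfg = FitConfig()
        e = np.full(30, 2.0)  # all equal to theta = mu0: no residual variance
        t = np.full(30, 60.0)
        _, s2 = update_alpha_sigma2_gene(e, init, [2.0], t, np.ones(30), cfg,
                                         alpha=1.0, sigma2=1.0)
        assert s2 < 5 * cfg.sigma2_min

    def test_alpha_recovery_on_simulated_gene(self):
        # known (alpha, sigma2), 500 cells, everything else at truth
        alpha_true, sigma2_true, theta, mu0, var0 = 1.0, 1.2, 4.0, 0.0, 0.2
        cfg = FitConfig()
        rel_errs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            t = rng.uniform(0.05, 2.0, size=500)
            a = np.exp(-alpha_true * t)
            mean = a * mu0 + (1 - a) * theta
            var = sigma2_true * (1 - a**2) / (2 * alpha_true) + a**2 * var0
            e = rng.normal(mean, np.sqrt(var))
            init = InitialDistribution(mu0=[mu0], var0=[var0])
            a_hat, _ = update_alpha_sigma2_gene(e, init, [theta], t, np.ones(500),
                                                cfg, alpha=1.5, sigma2=1.0)
            rel_errs.append(abs(a_hat - alpha_true) / alpha_true)
        assert np.median(rel_errs) < 0.2


class TestPseudotimeUpdate:
    def _model(self):
        G = 5
        params = OUGeneParams(alpha=np.full(G, 1.0), sigma2=np.full(G, 0.5),
                              theta=np.linspace(2, 4, G)[:, None])
        init = InitialDistribution(mu0=np.zeros(G), var0=np.full(G, 0.2))
        return params, init

    def test_progenitor_pattern_goes_to_t_min(self):
        params, init = self._model()
        cfg = FitConfig()
        t = update_pseudotime_cell(init.mu0, params, init, [1.0], [1.0], 0.5, cfg)
        assert t < 0.05

    def test_attractor_pattern_goes_large(self):
        params, init = self._model()
        cfg = FitConfig()
        t = update_pseudotime_cell(params.theta[:, 0], params, init, [1.0], [1.0],
                                   0.5, cfg)
        assert t > 3.0

    def test_grid_oracle_agreement(self):
        params, init = self._model()
        cfg = FitConfig()
        rng = np.random.default_rng(9)
        e = rng.normal(1.5, 0.5, size=5)

        def cell_obj(t):
            return float(_cell_lineage_loglik(
                e[None, :], np.array([t]), params.alpha, params.sigma2,
                params.theta, init.mu0, init.var0)[0, 0])

        t_hat = update_pseudotime_cell(e, params, init, [1.0], [1.0], 1.0, cfg)
        grid = np.linspace(cfg.t_bounds[0], cfg.t_bounds[1], 10_000)
        grid_best = max(cell_obj(t) for t in grid)
        assert cell_obj(t_hat) >= grid_best - 1e-6


class TestResponsibilities:
    def _fit(self, theta, pi, t, gamma):
        G = theta.shape[0]
        return MixtureFit(
            K=theta.shape[1], pi=pi,
            params=OUGeneParams(alpha=np.ones(G), sigma2=np.ones(G), theta=theta),
            cells=CellLatentState(t=t, gamma=gamma),
            init=InitialDistribution(mu0=np.zeros(G), var0=np.full(G, 0.2)),
            loglik_trace=[0.0],
        )

    def test_indistinguishable_lineages_return_pi(self, small_matrix):
        G = small_matrix.n_genes
        theta = np.tile(np.linspace(1, 2, G)[:, None], (1, 2))
        fit = self._fit(theta, np.array([0.7, 0.3]),
                        np.full(small_matrix.n_cells, 0.5),
                        np.full((small_matrix.n_cells, 2), 0.5))
        gamma = responsibilities(small_matrix, fit)
        np.testing.assert_allclose(gamma, np.tile([0.7, 0.3], (small_matrix.n_cells, 1)))

    def test_single_lineage_is_one(self, small_matrix):
        G = small_matrix.n_genes
        fit = self._fit(np.ones((G, 1)), np.array([1.0]),
                        np.full(small_matrix.n_cells, 0.5),
                        np.ones((small_matrix.n_cells, 1)))
        np.testing.assert_allclose(responsibilities(small_matrix, fit), 1.0)

    def test_well_separated_attractors_confident(self):
        sim = simulate_dataset(SimulationSpec(
            C=150, G=20, K=2, theta_range=(8.0, 10.0), mirror_attractors=True,
            t_range=(1.5, 2.0), seed=21))
        fit = self._fit(sim.params.theta, np.array([0.5, 0.5]), sim.cells.t,
                        sim.cells.gamma)
        fit = MixtureFit(K=2, pi=fit.pi,
                         params=OUGeneParams(alpha=sim.params.alpha,
                                             sigma2=sim.params.sigma2,
                                             theta=sim.params.theta),
                         cells=fit.cells, init=sim.init, loglik_trace=[0.0])
        gamma = responsibilities(sim.expression, fit)
        frac_confident = (gamma.max(axis=1) > 0.99).mean()
        assert frac_confident > 0.99
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-12)


class TestMixtureWeights:
    @pytest.mark.parametrize("gamma,expected", [
        ([[1, 0], [1, 0], [0, 1]], [2 / 3, 1 / 3]),
        ([[0.5, 0.5], [0.5, 0.5]], [0.5, 0.5]),
    ])
    def test_examples(self, gamma, expected):
        np.testing.assert_allclose(update_mixture_weights(np.array(gamma, float)),
                                   expected)

    def test_column_means(self):
        rng = np.random.default_rng(2)
        raw = rng.uniform(size=(4, 3))
        gamma = raw / raw.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(update_mixture_weights(gamma),
                                   gamma.mean(axis=0), atol=1e-12)


class TestAssignLineage:
    def test_examples(self):
        assert assign_lineage(np.array([[0.99, 0.01]]))[0] == 0
        assert assign_lineage(np.array([[0.5, 0.5]]))[0] == "uncertain"

    def test_threshold_sweep_monotone(self):
        rng = np.random.default_rng(4)
        raw = rng.uniform(size=(50, 2))
        gamma = raw / raw.sum(axis=1, keepdims=True)
        prev = None
        for thr in np.linspace(0.05, 0.95, 19):
            counts = np.array([
                sum(1 for a in assign_lineage(gamma, thr) if a == k)
                for k in range(2)
            ])
            if prev is not None:
                assert np.all(counts <= prev)
            prev = counts


class TestFits:
    def test_single_lineage_recovery(self):
        sim = simulate_dataset(SimulationSpec(C=60, G=80, seed=1))
        t0 = sp_pseudotime(sim.expression, sim.init)
        fit = fit_single_lineage(sim.expression, sim.init, t0,
                                 FitConfig(max_iter=60, seed=1))
        r = np.corrcoef(sim.cells.t, fit.cells.t)[0, 1]
        assert r * r >= 0.9
        d = np.diff(fit.loglik_trace)
        assert np.all(d >= -1e-6)

    def test_no_progression_signal(self):
        rng = np.random.default_rng(8)
        from oudiff.types import ExpressionMatrix
        mu0 = rng.uniform(-1, 1, size=20)
        E = ExpressionMatrix(
            values=rng.normal(mu0, 0.3, size=(40, 20)),
            cell_ids=[f"c{i}" for i in range(40)],
            gene_ids=[f"g{j}" for j in range(20)])
        init = InitialDistribution(mu0=mu0, var0=np.full(20, 0.09))
        fit = fit_single_lineage(E, init, np.full(40, 0.3),
                                 FitConfig(max_iter=20, seed=8))
        assert np.median(fit.cells.t) < 0.1

    def test_determinism(self):
        sim = simulate_dataset(SimulationSpec(C=30, G=15, seed=6))
        t0 = sp_pseudotime(sim.expression, sim.init)
        cfg = FitConfig(max_iter=10, seed=6)
        f1 = fit_single_lineage(sim.expression, sim.init, t0, cfg)
        f2 = fit_single_lineage(sim.expression, sim.init, t0, cfg)
        np.testing.assert_array_equal(f1.loglik_trace, f2.loglik_trace)
        np.testing.assert_array_equal(f1.cells.t, f2.cells.t)
        np.testing.assert_array_equal(f1.params.alpha, f2.params.alpha)

    def test_k1_mixture_equals_single_lineage(self):
        sim = simulate_dataset(SimulationSpec(C=30, G=15, seed=6))
        t0 = sp_pseudotime(sim.expression, sim.init)
        cfg = FitConfig(max_iter=10, seed=6)
        f1 = fit_single_lineage(sim.expression, sim.init, t0, cfg)
        f2 = fit_mixture(sim.expression, sim.init, 1, t0, cfg)
        np.testing.assert_array_equal(f1.cells.t, f2.cells.t)
        np.testing.assert_array_equal(f1.loglik_trace, f2.loglik_trace)

    def test_lineage_label_swap_symmetry(self):
        # permuting lineage columns leaves every cell's marginal unchanged
        rng = np.random.default_rng(12)
        G, C = 10, 25
        theta = rng.normal(size=(G, 2))
        alpha, sigma2 = rng.uniform(0.5, 2, G), rng.uniform(0.5, 2, G)
        mu0, var0 = rng.normal(size=G), rng.uniform(0.1, 0.5, G)
        E = rng.normal(size=(C, G))
        t = rng.uniform(0.1, 2, C)
        from oudiff.inference import _marginal_loglik
        pi = np.array([0.6, 0.4])
        ll = _marginal_loglik(E, t, alpha, sigma2, theta, mu0, var0, pi)
        ll_swap = _marginal_loglik(E, t, alpha, sigma2, theta[:, ::-1], mu0, var0,
                                   pi[::-1])
        assert ll == pytest.approx(ll_swap, abs=1e-9)

    def test_mixture_bifurcation_recovery(self):
        from oudiff.evaluation import lineage_pr_auc
        sim = simulate_dataset(SimulationSpec(C=80, G=30, K=2,
                                              mirror_attractors=True, seed=13))
        t0 = sp_pseudotime(sim.expression, sim.init)
        fit = fit_mixture(sim.expression, sim.init, 2, t0,
                          FitConfig(max_iter=40, seed=13, n_restarts=2))
        labels = sim.lineage == 1
        auc = max(lineage_pr_auc(fit.cells.gamma[:, k], labels) for k in range(2))
        assert auc >= 0.95
        assert np.all(np.diff(fit.loglik_trace) >= -1e-6)
        assert fit.pi.sum() == pytest.approx(1.0)
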
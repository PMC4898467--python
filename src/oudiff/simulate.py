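"""Synthetic single-cell expression generators for the OU differentiation model.

The generator draws per-gene OU parameters and per-cell pseudo-times, then
samples expression directly from the exact OU marginal (initial state
integrated out), so there is no discretization error. Two constructions used
for benchmarking are included: multiplicative-mean uniform noise injection
and sign-inverted "pseudogene" columns that create a symmetric bifurcation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import marginal_moments_matrix
from .types import (
    CellLatentState,
    DataError,
    ExpressionMatrix,
    InitialDistribution,
    OUGeneParams,
    ParameterError,
)

__all__ = [
    "SimulationSpec",
    "NoiseSpec",
    "SimulationResult",
    "simulate_dataset",
    "add_noise",
    "make_pseudogenes",
    "estimate_initial",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the simulation study.

    Defaults are the validation design: 100 cells x 500 genes, single
    lineage, gene parameters drawn uniformly from fixed ranges and pseudo-
    times uniform on ``t_range``. ``theta_range`` is an offset added to each
    gene's initial mean, so attractors stay anchored to the progenitor state.
    With ``mirror_attractors`` (K = 2) the second lineage's attractor is the
    reflection of the first about the initial mean, the geometry of the
    pseudogene construction.
    """

    C: int = 100
    G: int = 500
    K: int = 1
    alpha_range: tuple[float, float] = (0.5, 2.0)
    sigma2_range: tuple[float, float] = (0.5, 2.0)
    theta_range: tuple[float, float] = (-5.0, 5.0)
    t_range: tuple[float, float] = (0.0, 2.0)
    mu0_range: tuple[float, float] = (-2.0, 2.0)
    var0_range: tuple[float, float] = (0.1, 0.5)
    pi_true: tuple[float, ...] | None = None
    mirror_attractors: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.C < 1 or self.G < 1 or self.K < 1:
            raise ParameterError("C, G and K must be >= 1")
        for name in ("alpha_range", "sigma2_range", "var0_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ParameterError(f"{name} must be a non-negative ordered interval")
        for name in ("theta_range", "t_range", "mu0_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ParameterError(f"{name} must be ordered")
        if self.t_range[0] < 0:
            raise ParameterError("pseudo-times must be non-negative")
        if self.alpha_range[0] <= 0 or self.sigma2_range[0] <= 0:
            raise ParameterError("alpha and sigma2 must be strictly positive")
        if self.mirror_attractors and self.K != 2:
            raise ParameterError("mirrored attractors require K = 2")
        if self.pi_true is not None and (
            len(self.pi_true) != self.K or abs(sum(self.pi_true) - 1.0) > 1e-9
        ):
            raise ParameterError("pi_true must be a length-K probability vector")


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative-mean uniform noise: add mean(E_g) * U[0, epsilon]."""

    epsilon: float
    seed: int = 0

    def __post_init__(self):
        if self.epsilon < 0:
            raise ParameterError("epsilon must be non-negative")


#: the benchmark noise grid
NOISE_LEVELS = (0.0, 0.5, 1.0)


@dataclass(frozen=True)
class SimulationResult:
    expression: ExpressionMatrix
    params: OUGeneParams
    init: InitialDistribution
    cells: CellLatentState
    lineage: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


def simulate_dataset(spec: SimulationSpec) -> SimulationResult:
    """Draw a dataset from the OU marginal with heterogeneous gene parameters.

    Per gene: alpha, sigma2 uniform on their ranges, per-lineage attractor
    theta_gk = mu0_g + offset (offset uniform on ``theta_range``); per cell:
    t_c uniform on ``t_range`` and a lineage drawn from ``pi_true``. Each
    E_cg is a single draw from N(mu_t, var_t) with the exact marginal
    moments. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    C, G, K = spec.C, spec.G, spec.K
    mu0 = rng.uniform(*spec.mu0_range, size=G)
    var0 = rng.uniform(*spec.var0_range, size=G)
    alpha = rng.uniform(*spec.alpha_range, size=G)
    sigma2 = rng.uniform(*spec.sigma2_range, size=G)
    if spec.mirror_attractors:
        offset = rng.uniform(*spec.theta_range, size=(G, 1))
        theta = np.hstack([mu0[:, None] + offset, mu0[:, None] - offset])
    else:
        theta = mu0[:, None] + rng.uniform(*spec.theta_range, size=(G, K))
    pi = np.full(K, 1.0 / K) if spec.pi_true is None else np.asarray(spec.pi_true)
    t = rng.uniform(*spec.t_range, size=C)
    lineage = rng.choice(K, size=C, p=pi)
    mean, var = marginal_moments_matrix(t, alpha, sigma2, theta, mu0, var0)
    mean_sel = mean[np.arange(C), :, lineage]
    values = rng.normal(mean_sel, np.sqrt(var))
    gamma = np.zeros((C, K))
    gamma[np.arange(C), lineage] = 1.0
    return SimulationResult(
        expression=ExpressionMatrix(
            values=values,
            cell_ids=[f"cell{c:04d}" for c in range(C)],
            gene_ids=[f"gene{g:04d}" for g in range(G)],
        ),
        params=OUGeneParams(alpha=alpha, sigma2=sigma2, theta=theta),
        init=InitialDistribution(mu0=mu0, var0=var0),
        cells=CellLatentState(t=t, gamma=gamma),
        lineage=lineage,
    )


def add_noise(E: ExpressionMatrix, noise: NoiseSpec) -> ExpressionMatrix:
    """Add gene-mean-scaled uniform noise: E'_cg = E_cg + mean_c(E_cg) * U[0, eps]."""
    if noise.epsilon == 0:
        return E
    rng = np.random.default_rng(noise.seed)
    gene_mean = E.values.mean(axis=0)
    u = rng.uniform(0.0, noise.epsilon, size=E.values.shape)
    return ExpressionMatrix(values=E.values + gene_mean[None, :] * u,
                            cell_ids=E.cell_ids, gene_ids=E.gene_ids)


def make_pseudogenes(E: ExpressionMatrix, mu0, fraction: float = 0.5,
                     seed: int = 0):
    """Append sign-inverted pseudogene columns that encode a hidden bifurcation.

    A random ``fraction`` of cells keep the raw values in the pseudogene
    columns; the remaining cells get the reflection about the initial mean,
    E'_cg = -2 E_cg + mu0_g. Returns the widened matrix and the hidden
    keep/invert partition as a boolean array (True = kept lineage). Note the
    transform is not an involution: applying it twice gives 4 E - mu0.
    """
    if not (0.0 < fraction < 1.0):
        raise ParameterError("fraction must lie in (0, 1)")
    mu0 = np.asarray(mu0, dtype=float)
    if mu0.shape != (E.n_genes,):
        raise DataError("mu0 length must equal the gene count")
    rng = np.random.default_rng(seed)
    n_keep = int(round(fraction * E.n_cells))
    keep_idx = rng.choice(E.n_cells, size=n_keep, replace=False)
    keep = np.zeros(E.n_cells, dtype=bool)
    keep[keep_idx] = True
    pseudo = np.where(keep[:, None], E.values, -2.0 * E.values + mu0[None, :])
    values = np.hstack([E.values, pseudo])
    gene_ids = list(E.gene_ids) + [f"{g}_pg" for g in E.gene_ids]
    return (
        ExpressionMatrix(values=values, cell_ids=E.cell_ids, gene_ids=gene_ids),
        keep,
    )


def estimate_initial(E0: ExpressionMatrix, var_floor: float = 1e-6) -> InitialDistribution:
    """Estimate the progenitor distribution from a progenitor-cell submatrix.

    mu0_g is the mean over progenitor cells and var0_g the biased
    (divide-by-count) variance, floored at ``var_floor``.
    """
    if E0.n_cells < 1:
        raise DataError("need at least one progenitor cell")
    mu0 = E0.values.mean(axis=0)
    var0 = np.mean((E0.values - mu0[None, :]) ** 2, axis=0)
    return InitialDistribution(mu0=mu0, var0=var0, var_floor=var_floor)
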
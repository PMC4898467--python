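"""Shared containers and exceptions.

All arrays are plain numpy; matrices are cells-in-rows (C x G). Containers
validate their invariants on construction so downstream numerics can assume
well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

VAR_FLOOR = 1e-12


class OudiffError(Exception):
    """Base class for all package errors."""


class ParameterError(OudiffError, ValueError):
    """A model parameter is outside its domain (e.g. alpha <= 0)."""


class DataError(OudiffError, ValueError):
    """Malformed input data (shape, ids, missing values, parse failures)."""


class UndefinedScoreError(OudiffError, ValueError):
    """A score's denominator is empty (e.g. all pseudo-times tied)."""


def _as_1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise DataError(f"{name} must be 1-dimensional, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise DataError(f"{name} contains non-finite values")
    return a


@dataclass(frozen=True)
class OUGeneParams:
    """Per-gene OU parameters.

    alpha : (G,) relaxation strength toward the attractor, > 0, in units of
        inverse pseudo-time.
    sigma2 : (G,) diffusion variance rate, > 0.
    theta : (G, K) attractor expression level, one column per lineage.
    """

    alpha: np.ndarray
    sigma2: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        alpha = _as_1d(self.alpha, "alpha")
        sigma2 = _as_1d(self.sigma2, "sigma2")
        theta = np.asarray(self.theta, dtype=float)
        if theta.ndim == 1:
            theta = theta[:, None]
        if theta.ndim != 2:
            raise DataError(f"theta must be (G,) or (G, K), got shape {theta.shape}")
        if not np.all(np.isfinite(theta)):
            raise DataError("theta contains non-finite values")
        if np.any(alpha <= 0):
            raise ParameterError("alpha must be strictly positive")
        if np.any(sigma2 <= 0):
            raise ParameterError("sigma2 must be strictly positive")
        if not (len(alpha) == len(sigma2) == theta.shape[0]):
            raise DataError("alpha, sigma2 and theta must agree on the gene count")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "sigma2", sigma2)
        object.__setattr__(self, "theta", theta)

    @property
    def n_genes(self) -> int:
        return len(self.alpha)

    @property
    def n_lineages(self) -> int:
        return self.theta.shape[1]


@dataclass(frozen=True)
class InitialDistribution:
    """Gaussian initial (progenitor) state per gene: S_g ~ N(mu0, var0)."""

    mu0: np.ndarray
    var0: np.ndarray
    var_floor: float = 1e-6

    def __post_init__(self):
        mu0 = _as_1d(self.mu0, "mu0")
        var0 = _as_1d(self.var0, "var0")
        if len(mu0) != len(var0):
            raise DataError("mu0 and var0 must have equal length")
        if self.var_floor <= 0:
            raise ParameterError("var_floor must be positive")
        if np.any(var0 < 0):
            raise ParameterError("var0 must be non-negative")
        object.__setattr__(self, "mu0", mu0)
        object.__setattr__(self, "var0", np.maximum(var0, self.var_floor))

    @property
    def n_genes(self) -> int:
        return len(self.mu0)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Dense C x G expression matrix with unique cell and gene identifiers."""

    values: np.ndarray
    cell_ids: Sequence[str]
    gene_ids: Sequence[str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise DataError(f"expression values must be 2-dimensional, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise DataError("expression matrix contains non-finite values")
        cells = list(map(str, self.cell_ids))
        genes = list(map(str, self.gene_ids))
        if v.shape != (len(cells), len(genes)):
            raise DataError(
                f"shape {v.shape} inconsistent with {len(cells)} cells x {len(genes)} genes"
            )
        if v.shape[0] < 2 or v.shape[1] < 1:
            raise DataError("need at least 2 cells and 1 gene")
        if len(set(cells)) != len(cells):
            raise DataError("duplicate cell ids")
        if len(set(genes)) != len(genes):
            raise DataError("duplicate gene ids")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "cell_ids", cells)
        object.__setattr__(self, "gene_ids", genes)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CellLatentState:
    """Per-cell latent state: pseudo-time t_c and lineage responsibilities."""

    t: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        t = _as_1d(self.t, "t")
        gamma = np.asarray(self.gamma, dtype=float)
        if gamma.ndim != 2 or gamma.shape[0] != len(t):
            raise DataError("gamma must be (C, K) matching t")
        if np.any(t < 0):
            raise ParameterError("pseudo-times must be non-negative")
        if np.any(gamma < -1e-12) or np.any(gamma > 1 + 1e-12):
            raise ParameterError("responsibilities must lie in [0, 1]")
        if np.any(np.abs(gamma.sum(axis=1) - 1.0) > 1e-9):
            raise ParameterError("each responsibility row must sum to 1")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "gamma", gamma)

    @property
    def n_cells(self) -> int:
        return len(self.t)

    @property
    def n_lineages(self) -> int:
        return self.gamma.shape[1]


@dataclass(frozen=True)
class MixtureFit:
    """Result of fitting the (mixture) OU model."""

    K: int
    pi: np.ndarray
    params: OUGeneParams
    cells: CellLatentState
    init: InitialDistribution
    loglik_trace: np.ndarray
    gene_ids: Sequence[str] = field(default_factory=list)
    cell_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self):
        pi = _as_1d(self.pi, "pi")
        if self.K < 1:
            raise ParameterError("K must be >= 1")
        if len(pi) != self.K:
            raise DataError("pi length must equal K")
        if np.any(pi < -1e-12) or abs(pi.sum() - 1.0) > 1e-9:
            raise ParameterError("pi must be a probability vector")
        if self.params.n_lineages != self.K:
            raise DataError("theta column count must equal K")
        if self.cells.n_lineages != self.K:
            raise DataError("gamma column count must equal K")
        trace = _as_1d(self.loglik_trace, "loglik_trace")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "loglik_trace", trace)
        object.__setattr__(self, "gene_ids", list(map(str, self.gene_ids)))
        object.__setattr__(self, "cell_ids", list(map(str, self.cell_ids)))

    @property
    def final_loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def n_iter(self) -> int:
        return len(self.loglik_trace)
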
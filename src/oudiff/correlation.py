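"""Time-trend-removing standardization and gene-gene correlation screens.

Any two genes that merely share a time trend along differentiation correlate
strongly in raw data. Standardizing each observation by its model-implied
time-dependent mean and variance,

    Z_cg = (E_cg - mu_{t_c g}) / sigma2_{t_c g},

removes that trend, so residual correlation (C_Std) indicates covariation the
gene-independent model cannot explain - a signature of regulation. The
divisor is the variance, as the model defines it; a standard-deviation
divisor is available and leaves Pearson correlations unchanged (they are
invariant to per-column scaling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import marginal_moments_matrix
from .types import DataError, ExpressionMatrix, MixtureFit

__all__ = [
    "StandardizedMatrix",
    "standardize",
    "correlation_matrix",
    "rank_gene_pairs",
    "mean_group_correlation",
]


@dataclass(frozen=True)
class StandardizedMatrix:
    """Model-standardized expression Z_cg plus provenance."""

    values: np.ndarray
    cell_ids: list
    gene_ids: list
    fit: MixtureFit
    divisor: str = "var"


def standardize(E: ExpressionMatrix, fit: MixtureFit, divisor: str = "var",
                lineage: int | None = None) -> StandardizedMatrix:
    """Standardize expression by each cell's model-implied moments.

    For a mixture fit each cell uses the attractor of its argmax-gamma
    lineage (most responsibilities are near 1 in practice). ``lineage``
    restricts the output to cells hard-assigned to that lineage, for
    per-lineage correlation analysis.
    """
    if divisor not in ("var", "sd"):
        raise DataError("divisor must be 'var' or 'sd'")
    if fit.params.n_genes != E.n_genes or fit.cells.n_cells != E.n_cells:
        raise DataError("fit does not cover this expression matrix")
    mean, var = marginal_moments_matrix(
        fit.cells.t, fit.params.alpha, fit.params.sigma2, fit.params.theta,
        fit.init.mu0, fit.init.var0,
    )  # mean (C, G, K), var (C, G)
    assign = np.argmax(fit.cells.gamma, axis=1)
    mean_sel = mean[np.arange(E.n_cells), :, assign]
    if np.any(var <= 1e-12):
        raise DataError("model variance at the floor; standardization undefined")
    denom = var if divisor == "var" else np.sqrt(var)
    Z = (E.values - mean_sel) / denom
    cells = list(E.cell_ids)
    if lineage is not None:
        keep = assign == lineage
        Z = Z[keep]
        cells = [c for c, m in zip(cells, keep) if m]
    return StandardizedMatrix(values=Z, cell_ids=cells, gene_ids=list(E.gene_ids),
                              fit=fit, divisor=divisor)


def _values_and_genes(M):
    if isinstance(M, (ExpressionMatrix, StandardizedMatrix)):
        return np.asarray(M.values, dtype=float), list(M.gene_ids)
    V = np.asarray(M, dtype=float)
    return V, [f"g{j}" for j in range(V.shape[1])]


def correlation_matrix(M) -> pd.DataFrame:
    """G x G Pearson correlation of the columns of a cells-by-genes matrix.

    Applied to raw expression this is C_Raw; applied to a standardized matrix
    it is C_Std.
    """
    V, genes = _values_and_genes(M)
    sd = V.std(axis=0)
    if np.any(sd == 0):
        bad = [genes[j] for j in np.flatnonzero(sd == 0)]
        raise DataError(f"correlation undefined for constant gene(s): {', '.join(bad)}")
    corr = np.corrcoef(V, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=genes, columns=genes)


def rank_gene_pairs(corr: pd.DataFrame, query_genes, n_top: int,
                    use_abs: bool = False) -> list[tuple[str, str, float]]:
    """Top (query, other) gene pairs by descending correlation.

    Positive correlations are ranked by default (set ``use_abs`` to rank by
    magnitude); self-pairs are excluded and ties break on (query, other) ids.
    """
    genes = list(corr.columns)
    unknown = [q for q in query_genes if q not in corr.index]
    if unknown:
        raise DataError(f"unknown gene id(s): {', '.join(map(str, unknown))}")
    pairs = []
    for q in query_genes:
        row = corr.loc[q]
        for g in genes:
            if g == q:
                continue
            r = float(row[g])
            key = abs(r) if use_abs else r
            pairs.append((key, str(q), str(g), r))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    return [(q, g, r) for _, q, g, r in pairs[:n_top]]


def mean_group_correlation(corr: pd.DataFrame, candidate_gene: str, group_genes) -> float:
    """Average correlation between a candidate gene and a gene group.

    The candidate is excluded from the group if present.
    """
    if candidate_gene not in corr.index:
        raise DataError(f"unknown gene id: {candidate_gene}")
    members = [g for g in group_genes if g != candidate_gene]
    if not members:
        raise DataError("group is empty after excluding the candidate")
    missing = [g for g in members if g not in corr.columns]
    if missing:
        raise DataError(f"unknown gene id(s): {', '.join(map(str, missing))}")
    return float(corr.loc[candidate_gene, members].mean())
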
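"""Reading and writing the TSV/CSV/JSON formats used by the pipeline.

Expression matrices are dense cells-in-rows tables: first column ``cell_id``,
header row gene ids, numeric body. The tab/comma dialect is auto-detected
from the header; mixed dialects are rejected. Fit results serialize to a
directory of three TSVs (gene parameters, cell states, scalars) plus a JSON
metadata file carrying the schema version and the log-likelihood trace.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CellLatentState,
    DataError,
    ExpressionMatrix,
    InitialDistribution,
    MixtureFit,
    OUGeneParams,
)

SCHEMA_VERSION = "1"

__all__ = [
    "read_expression", "write_expression",
    "read_init", "write_init",
    "read_labels", "read_pseudotime", "write_pseudotime",
    "write_fit", "read_fit",
]


def _detect_sep(path: Path) -> str:
    header = path.read_text().splitlines()
    if not header:
        raise DataError(f"{path}: empty file")
    line = header[0]
    has_tab, has_comma = "\t" in line, "," in line
    if has_tab and has_comma:
        raise DataError(f"{path}: mixed tab/comma dialect in header")
    if not has_tab and not has_comma:
        raise DataError(f"{path}: header contains neither tabs nor commas")
    return "\t" if has_tab else ","


def _read_table(path, index_name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: no such file")
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                         keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"{path}: parse failure: {exc}") from exc
    df.index = df.index.astype(str)
    return df


def _to_numeric(df: pd.DataFrame, path) -> np.ndarray:
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            # numpy's parser is correctly rounded (pandas' is not)
            arr = np.asarray(df[col].values, dtype=float)
        except ValueError:
            arr = None
        if arr is None or np.isnan(arr).any():
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna().values
            i = int(np.flatnonzero(bad)[0])
            raw = str(df[col].iloc[i])
            kind = ("missing value" if raw.strip() in ("", "NA", "NaN", "nan")
                    else "malformed numeric")
            raise DataError(
                f"{path}: {kind} at cell '{df.index[i]}', gene '{col}' (got '{raw}')"
            )
        values[:, j] = arr
    return values


def read_expression(path, transpose: bool = False) -> ExpressionMatrix:
    """Read a cells-by-genes expression table (``transpose`` for genes-in-rows)."""
    df = _read_table(path, "cell_id")
    values = _to_numeric(df, path)
    cells, genes = list(df.index), list(df.columns)
    if transpose:
        values, cells, genes = values.T, genes, cells
    return ExpressionMatrix(values=values, cell_ids=cells, gene_ids=genes)


def write_expression(E: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(E.values, index=pd.Index(E.cell_ids, name="cell_id"),
                      columns=E.gene_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_init(path) -> InitialDistribution:
    """Read a per-gene initial-distribution table (gene_id, mu0, var0)."""
    df = _read_table(path, "gene_id")
    for col in ("mu0", "var0"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column '{col}'")
    mu0 = pd.to_numeric(df["mu0"], errors="raise").values
    var0 = pd.to_numeric(df["var0"], errors="raise").values
    return InitialDistribution(mu0=mu0, var0=var0)


def write_init(init: InitialDistribution, gene_ids, path) -> None:
    pd.DataFrame(
        {"mu0": init.mu0, "var0": init.var0},
        index=pd.Index(gene_ids, name="gene_id"),
    ).to_csv(path, sep="\t", float_format="%.17g")


def read_pseudotime(path) -> pd.Series:
    df = _read_table(path, "cell_id")
    col = "t" if "t" in df.columns else df.columns[0]
    return pd.to_numeric(df[col], errors="raise")


def write_pseudotime(cell_ids, t, path) -> None:
    pd.DataFrame({"t": np.asarray(t, dtype=float)},
                 index=pd.Index(cell_ids, name="cell_id")).to_csv(
        path, sep="\t", float_format="%.17g")


def read_labels(path) -> pd.DataFrame:
    """Read a per-cell label table (experimental time and/or lineage columns)."""
    return _read_table(path, "cell_id")


def write_fit(fit: MixtureFit, out_dir) -> None:
    """Serialize a fit as three TSVs plus JSON run metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = fit.gene_ids or [f"g{j}" for j in range(fit.params.n_genes)]
    cells = fit.cell_ids or [f"c{j}" for j in range(fit.cells.n_cells)]
    gene_tab = pd.DataFrame(
        {"alpha": fit.params.alpha, "sigma2": fit.params.sigma2},
        index=pd.Index(genes, name="gene_id"),
    )
    for k in range(fit.K):
        gene_tab[f"theta_{k + 1}"] = fit.params.theta[:, k]
    gene_tab["mu0"] = fit.init.mu0
    gene_tab["var0"] = fit.init.var0
    gene_tab.to_csv(out / "gene_params.tsv", sep="\t", float_format="%.17g")

    cell_tab = pd.DataFrame({"t": fit.cells.t}, index=pd.Index(cells, name="cell_id"))
    for k in range(fit.K):
        cell_tab[f"gamma_{k + 1}"] = fit.cells.gamma[:, k]
    cell_tab.to_csv(out / "cell_states.tsv", sep="\t", float_format="%.17g")

    scalars = pd.DataFrame(
        {"name": ["K"] + [f"pi_{k + 1}" for k in range(fit.K)] + ["final_loglik", "n_iter"],
         "value": [fit.K, *fit.pi, fit.final_loglik, fit.n_iter]}
    )
    scalars.to_csv(out / "scalars.tsv", sep="\t", index=False)

    meta = {
        "schema_version": SCHEMA_VERSION,
        "K": fit.K,
        "loglik_trace": [float(x) for x in fit.loglik_trace],
    }
    (out / "run_meta.json").write_text(json.dumps(meta, indent=1))


def read_fit(out_dir) -> MixtureFit:
    """Reload a serialized fit; inverse of :func:`write_fit` to 1e-12."""
    out = Path(out_dir)
    meta_path = out / "run_meta.json"
    if not meta_path.exists():
        raise DataError(f"{out}: missing run_meta.json")
    meta = json.loads(meta_path.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise DataError(
            f"{out}: schema version {meta.get('schema_version')!r} != {SCHEMA_VERSION!r}"
        )
    K = int(meta["K"])
    gene_tab = pd.read_csv(out / "gene_params.tsv", sep="\t", index_col=0)
    cell_tab = pd.read_csv(out / "cell_states.tsv", sep="\t", index_col=0)
    for name, tab in (("gene_params.tsv", gene_tab), ("cell_states.tsv", cell_tab)):
        if len(tab) < 2 or tab.isna().any().any():
            bad = tab.isna().any(axis=1)
            line = int(np.flatnonzero(bad.values)[0]) + 2 if bad.any() else len(tab) + 1
            raise DataError(f"{out / name}: truncated or malformed near line {line}")
    scalars = pd.read_csv(out / "scalars.tsv", sep="\t")
    svals = dict(zip(scalars["name"], scalars["value"]))
    theta = np.column_stack([gene_tab[f"theta_{k + 1}"].values for k in range(K)])
    gamma = np.column_stack([cell_tab[f"gamma_{k + 1}"].values for k in range(K)])
    trace = np.asarray(meta["loglik_trace"], dtype=float)
    if len(trace) != int(float(svals["n_iter"])):
        raise DataError(f"{out}: loglik trace length disagrees with n_iter")
    return MixtureFit(
        K=K,
        pi=np.array([float(svals[f"pi_{k + 1}"]) for k in range(K)]),
        params=OUGeneParams(alpha=gene_tab["alpha"].values,
                            sigma2=gene_tab["sigma2"].values, theta=theta),
        cells=CellLatentState(t=cell_tab["t"].values, gamma=gamma),
        init=InitialDistribution(mu0=gene_tab["mu0"].values,
                                 var0=gene_tab["var0"].values),
        loglik_trace=trace,
        gene_ids=list(gene_tab.index.astype(str)),
        cell_ids=list(cell_tab.index.astype(str)),
    )
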
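"""Per-state reference expression profiles and figure-style summary tables.

A labelled single-cell count matrix is collapsed into a ``StateProfileMatrix``
holding, for every cell state, the mean normalized expression of each gene,
the mean linear-scale (pre-log) normalized expression used as the
deconvolution reference, and the fraction of the state's cells expressing
the gene (raw count > 0). Two presentation tables mirror the standard atlas
figures: a dot-plot table (percent expressing + per-gene z-scored mean
expression across the displayed states) and a per-gene z-scaled heatmap
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse


def _as_dense(X) -> np.ndarray:
    if sparse.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


@dataclass
class StateProfileMatrix:
    """Per-state expression reference.

    ``mean_expr``: genes x states mean of log1p-normalized expression.
    ``mean_linear``: genes x states mean of linear-scale normalized expression
    (counts-per-``scale``); the deconvolution dictionary, since mixtures are
    linear in counts but not in log space.
    ``frac_expr``: genes x states fraction of cells with raw count > 0.
    """

    mean_expr: pd.DataFrame
    mean_linear: pd.DataFrame
    frac_expr: pd.DataFrame
    n_cells: pd.Series

    def __post_init__(self) -> None:
        for df in (self.mean_linear, self.frac_expr):
            if not df.index.equals(self.mean_expr.index) or not df.columns.equals(
                self.mean_expr.columns
            ):
                raise ValueError("profile tables are not aligned")
        if ((self.frac_expr < 0) | (self.frac_expr > 1)).any().any():
            raise ValueError("frac_expr outside [0, 1]")
        if (self.mean_expr < 0).any().any():
            raise ValueError("mean_expr contains negative values")

    @property
    def genes(self) -> list[str]:
        return list(self.mean_expr.index)

    @property
    def states(self) -> list[str]:
        return list(self.mean_expr.columns)

    def to_csv(self, prefix) -> None:
        self.mean_expr.to_csv(f"{prefix}_mean_expr.csv")
        self.mean_linear.to_csv(f"{prefix}_mean_linear.csv")
        self.frac_expr.to_csv(f"{prefix}_frac_expr.csv")
        self.n_cells.rename("n_cells").to_csv(f"{prefix}_n_cells.csv")

    @classmethod
    def from_csv(cls, prefix) -> "StateProfileMatrix":
        mean_expr = pd.read_csv(f"{prefix}_mean_expr.csv", index_col=0)
        mean_linear = pd.read_csv(f"{prefix}_mean_linear.csv", index_col=0)
        frac_expr = pd.read_csv(f"{prefix}_frac_expr.csv", index_col=0)
        n_cells = pd.read_csv(f"{prefix}_n_cells.csv", index_col=0)["n_cells"]
        return cls(mean_expr, mean_linear, frac_expr, n_cells)


def normalize_counts(counts, scale: float = 1e4, log: bool = True) -> np.ndarray:
    """Library-size normalization: scale each cell to ``scale`` total counts, then log1p.

    ``counts`` is cells x genes (array or sparse). All-zero cells pass
    through as zero rows with a warning. With ``log=False`` the linear
    counts-per-``scale`` matrix is returned.
    """
    X = _as_dense(counts)
    if np.any(X < 0):
        raise ValueError("counts contain negative values")
    totals = X.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero cell(s) passed through unnormalized",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, totals)
    X = X * (scale / safe)[:, None]
    if log:
        X = np.log1p(X)
    return X


def build_profiles(
    counts, labels, gene_ids, scale: float = 1e4
) -> StateProfileMatrix:
    """Collapse a labelled cell x gene count matrix into per-state profiles.

    ``mean_expr`` averages log1p-normalized expression within each state,
    ``mean_linear`` averages the linear counts-per-``scale`` values, and
    ``frac_expr`` counts raw-positive cells. Errors on empty states.
    """
    labels = pd.Series(list(labels), name="state")
    X = _as_dense(counts)
    if X.shape[0] != len(labels):
        raise ValueError("label length does not match cell count")
    states = sorted(labels.unique())
    empty = [s for s in states if (labels == s).sum() == 0]
    if empty:
        raise ValueError(f"states with zero cells: {empty}")

    linear = normalize_counts(X, scale=scale, log=False)
    logged = np.log1p(linear)
    positive = X > 0

    mean_expr = {}
    mean_linear = {}
    frac = {}
    n_cells = {}
    for s in states:
        mask = (labels == s).to_numpy()
        mean_expr[s] = logged[mask].mean(axis=0)
        mean_linear[s] = linear[mask].mean(axis=0)
        frac[s] = positive[mask].mean(axis=0)
        n_cells[s] = int(mask.sum())

    idx = pd.Index(gene_ids, name="gene")
    return StateProfileMatrix(
        mean_expr=pd.DataFrame(mean_expr, index=idx),
        mean_linear=pd.DataFrame(mean_linear, index=idx),
        frac_expr=pd.DataFrame(frac, index=idx),
        n_cells=pd.Series(n_cells, name="n_cells"),
    )


def profiles_from_anndata(adata, state_key: str = "state", scale: float = 1e4):
    """Convenience wrapper: build profiles from an AnnData with a state column."""
    return build_profiles(
        adata.X, adata.obs[state_key].tolist(), list(adata.var_names), scale=scale
    )


def _zscore_rows(M: np.ndarray) -> np.ndarray:
    # population SD; constant rows map to 0 to keep heatmaps NaN-free
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    return np.where(sd == 0, 0.0, (M - mu) / np.where(sd == 0, 1.0, sd))


def _check_subset(requested, available, what: str) -> list:
    missing = [g for g in requested if g not in set(available)]
    if missing:
        raise KeyError(f"unknown {what}: {missing}")
    # collapse duplicates, keep first-seen order
    seen: dict = {}
    for g in requested:
        seen.setdefault(g, None)
    return list(seen)


def dotplot_table(
    profiles: StateProfileMatrix, genes, states
) -> pd.DataFrame:
    """Marker-enrichment dot-plot table: percent expressing and z-scored mean expression.

    ``pct_expressing`` is 100 x frac_expr; ``scaled_avg_expression`` is the
    per-gene z-score of mean expression across the *selected* states
    (population SD, constant genes score 0 everywhere).
    """
    genes = _check_subset(genes, profiles.genes, "gene(s)")
    states = _check_subset(states, profiles.states, "state(s)")
    means = profiles.mean_expr.loc[genes, states].to_numpy()
    scaled = _zscore_rows(means)
    rows = []
    for i, g in enumerate(genes):
        for j, s in enumerate(states):
            rows.append(
                {
                    "gene": g,
                    "state": s,
                    "pct_expressing": 100.0 * profiles.frac_expr.loc[g, s],
                    "scaled_avg_expression": scaled[i, j],
                }
            )
    return pd.DataFrame(rows)


def zscale_heatmap_table(
    profiles: StateProfileMatrix, genes, states
) -> pd.DataFrame:
    """Per-gene z-scaled mean-expression matrix (genes x states) for heatmaps."""
    genes = _check_subset(genes, profiles.genes, "gene(s)")
    states = _check_subset(states, profiles.states, "state(s)")
    means = profiles.mean_expr.loc[genes, states].to_numpy()
    return pd.DataFrame(_zscore_rows(means), index=pd.Index(genes, name="gene"), columns=states)
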
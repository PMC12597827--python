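"""Reference-based spot deconvolution by non-negative least squares.

Each spatially barcoded spot captures a mini bulk transcriptome of the
overlying tissue, modelled as a non-negative mixture of cell-state reference
profiles. Per spot, the counts-per-scale vector (no log transform -- mixtures
are linear in counts) is regressed onto the linear-scale state profiles
under a non-negativity constraint, and the weights are renormalized to the
simplex to give per-spot state proportions. Spots below a total-count floor
are masked rather than fitted.

The proportion-map contract isolates this estimator so a probabilistic
deconvolution model could be swapped in without touching downstream
co-detection analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from cardioniche.profiles import StateProfileMatrix, _as_dense


@dataclass
class SpatialSection:
    """One spatial section: spot x gene counts with coordinates and age metadata."""

    counts: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray  # (n_spots, 2) in section pixel units
    section_id: str
    pcw: float

    def __post_init__(self) -> None:
        self.counts = _as_dense(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.counts.shape[0]
        if len(self.spot_ids) != n or self.coords.shape != (n, 2):
            raise ValueError("spot ids / coords do not match count matrix")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.counts.shape[1] != len(self.gene_ids):
            raise ValueError("gene ids do not match count matrix")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]


@dataclass
class ProportionMap:
    """Per-section spots x states composition estimates.

    ``proportions`` rows are simplex-valued except masked spots (below the
    count floor), which are all-zero and flagged in ``mask``.
    """

    proportions: pd.DataFrame
    section_id: str
    coords: np.ndarray
    mask: np.ndarray  # True = masked (not fitted)
    pcw: float = float("nan")

    def __post_init__(self) -> None:
        P = self.proportions.to_numpy()
        if (P < -1e-12).any():
            raise ValueError("negative proportions")
        sums = P.sum(axis=1)
        ok = np.where(self.mask, np.abs(sums) < 1e-9, np.abs(sums - 1) < 1e-6)
        if not ok.all():
            raise ValueError("unmasked rows must sum to 1; masked rows must be zero")

    @property
    def states(self) -> list[str]:
        return list(self.proportions.columns)

    @property
    def spot_ids(self) -> list[str]:
        return list(self.proportions.index)

    def unmasked(self) -> pd.DataFrame:
        return self.proportions.loc[~self.mask]


def fit_proportions(
    section: SpatialSection,
    profiles: StateProfileMatrix,
    gene_subset: list[str] | None = None,
    min_counts: float = 100,
    ridge: float = 0.0,
    scale: float = 1e4,
) -> ProportionMap:
    """Estimate per-spot state proportions by NNLS against linear-scale profiles.

    Shared genes between section and reference (optionally intersected with
    ``gene_subset``) form the fitting space. Each spot is scaled to ``scale``
    total counts, solved with non-negative least squares, and the weights are
    renormalized to sum to 1. Spots with fewer than ``min_counts`` raw counts
    are masked. ``ridge > 0`` adds a Tikhonov penalty via row augmentation.
    """
    ref = profiles.mean_linear
    shared = [g for g in section.gene_ids if g in set(ref.index)]
    if gene_subset is not None:
        keep = set(gene_subset)
        shared = [g for g in shared if g in keep]
    if len(shared) < 2:
        raise ValueError("need at least 2 shared genes between section and reference")
    if len(profiles.states) < 2:
        raise ValueError("need at least 2 reference states")

    gene_pos = {g: i for i, g in enumerate(section.gene_ids)}
    cols = [gene_pos[g] for g in shared]
    Y = section.counts[:, cols]
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite counts")
    A = ref.loc[shared].to_numpy()  # genes x states

    cond = np.linalg.cond(A)
    if cond > 1e8:
        warnings.warn(
            f"reference profiles are ill-conditioned (cond={cond:.2e}); "
            "proportions may be unstable",
            stacklevel=2,
        )

    n_states = A.shape[1]
    if ridge > 0:
        A_fit = np.vstack([A, np.sqrt(ridge) * np.eye(n_states)])
    else:
        A_fit = A

    totals = section.counts.sum(axis=1)
    mask = totals < min_counts
    P = np.zeros((section.n_spots, n_states))
    for i in range(section.n_spots):
        if mask[i]:
            continue
        y = Y[i] * (scale / totals[i])
        if ridge > 0:
            y = np.concatenate([y, np.zeros(n_states)])
        w, _ = nnls(A_fit, y)
        s = w.sum()
        if s == 0:
            mask[i] = True
            continue
        P[i] = w / s

    return ProportionMap(
        proportions=pd.DataFrame(
            P, index=pd.Index(section.spot_ids, name="spot_id"), columns=profiles.states
        ),
        section_id=section.section_id,
        coords=section.coords,
        mask=mask,
        pcw=section.pcw,
    )


def prediction_map_table(pmap: ProportionMap, states: list[str]) -> pd.DataFrame:
    """Long-format (spot, x, y, state, proportion) table; masked spots excluded."""
    unknown = [s for s in states if s not in set(pmap.states)]
    if unknown:
        raise KeyError(f"unknown state(s): {unknown}")
    rows = []
    for i, spot in enumerate(pmap.spot_ids):
        if pmap.mask[i]:
            continue
        for s in states:
            rows.append(
                {
                    "spot_id": spot,
                    "x": pmap.coords[i, 0],
                    "y": pmap.coords[i, 1],
                    "state": s,
                    "proportion": pmap.proportions.iloc[i][s],
                }
            )
    return pd.DataFrame(rows, columns=["spot_id", "x", "y", "state", "proportion"])
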
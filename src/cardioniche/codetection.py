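"""Pairwise co-detection scores, the thresholded niche graph, and age-group stability.

Two cell states are "co-detected" when their deconvolved proportions peak in
the same spots: the co-detection score of a state pair is the Pearson
correlation of their per-spot proportions. Thresholding the score matrix
(strictly above 0.07 by default) yields the niche graph, whose connected
neighbourhoods correspond to recurring tissue microenvironments; a node's
degree counts its co-detected partners.

Aggregation across sections is either ``pooled`` (concatenate spots, one
correlation) or ``per_section_weighted`` (correlate within each section,
then average weighted by the section's unmasked spot count -- the default,
since it is immune to artifactual correlation induced by between-section
composition shifts). Zero-variance states propagate as missing values,
never as 0, and never create edges.

Temporal stability is assessed by partitioning sections into developmental
age groups (default postconceptional weeks 5.5-6, 7-8 and 9-14, with gaps
between printed intervals closed upward), recomputing the score matrix per
group, and comparing groups by the Pearson correlation of their
upper-triangle scores and the Jaccard index of their thresholded edge sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from cardioniche.deconvolution import ProportionMap

DEFAULT_THRESHOLD = 0.07
DEFAULT_AGE_BOUNDS = ((5.5, 6.0), (7.0, 8.0), (9.0, 14.0))


@dataclass
class CoDetectionMatrix:
    """States x states Pearson co-detection scores.

    Symmetric; diagonal 1 for states with nonzero variance; zero-variance
    states are NaN (missing), never 0.
    """

    scores: pd.DataFrame
    n_spots_used: int
    sections_used: list[str]
    aggregation: str

    def __post_init__(self) -> None:
        S = self.scores.to_numpy()
        finite = np.isfinite(S)
        if not np.array_equal(finite, finite.T):
            raise ValueError("missing-value pattern is not symmetric")
        if np.nanmax(np.abs(S - S.T)) > 1e-12 if finite.any() else False:
            raise ValueError("score matrix is not symmetric")
        if finite.any() and (np.nanmax(S) > 1 + 1e-12 or np.nanmin(S) < -1 - 1e-12):
            raise ValueError("scores outside [-1, 1]")

    @property
    def states(self) -> list[str]:
        return list(self.scores.columns)

    def upper_triangle(self) -> pd.Series:
        """Off-diagonal upper-triangle scores as a (state_a, state_b)-indexed series."""
        states = self.states
        idx, vals = [], []
        for i in range(len(states)):
            for j in range(i + 1, len(states)):
                idx.append((states[i], states[j]))
                vals.append(self.scores.iat[i, j])
        return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["state_a", "state_b"]))


@dataclass
class AgeGroupPartition:
    """Ordered PCW intervals and the section -> group assignment."""

    bounds: tuple[tuple[float, float], ...]
    assignment: dict[str, int]

    def sections_in(self, group: int) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]

    @property
    def n_groups(self) -> int:
        return len(self.bounds)

    def labels(self) -> list[str]:
        return [f"{lo:g}-{hi:g}" for lo, hi in self.bounds]

    def restrict(self, groups: set[int]) -> "AgeGroupPartition":
        """Drop empty groups and re-index the remaining ones contiguously."""
        order = sorted(groups)
        remap = {g: i for i, g in enumerate(order)}
        return AgeGroupPartition(
            bounds=tuple(self.bounds[g] for g in order),
            assignment={s: remap[g] for s, g in self.assignment.items()},
        )


def _pearson_matrix(P: np.ndarray) -> np.ndarray:
    """Pearson correlation of columns; zero-variance columns give NaN rows/cols."""
    n = P.shape[0]
    centered = P - P.mean(axis=0, keepdims=True)
    sd = centered.std(axis=0)
    cov = centered.T @ centered / n
    with np.errstate(invalid="ignore", divide="ignore"):
        R = cov / np.outer(sd, sd)
    R[np.abs(sd) < 1e-300, :] = np.nan
    R[:, np.abs(sd) < 1e-300] = np.nan
    np.clip(R, -1.0, 1.0, out=R)
    return R


def codetection_matrix(
    maps: list[ProportionMap], aggregation: str = "per_section_weighted"
) -> CoDetectionMatrix:
    """Pairwise Pearson co-detection scores over one or more proportion maps.

    ``pooled`` concatenates unmasked spots across sections before
    correlating; ``per_section_weighted`` correlates per section and
    averages with unmasked-spot-count weights (entries missing in a section
    are excluded pairwise from its weight).
    """
    if aggregation not in ("pooled", "per_section_weighted"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if not maps:
        raise ValueError("no proportion maps given")
    states = maps[0].states
    for m in maps[1:]:
        if m.states != states:
            raise ValueError(
                f"state sets differ between sections {maps[0].section_id!r} "
                f"and {m.section_id!r}"
            )
    if len(states) < 2:
        raise ValueError("need at least 2 states")

    blocks = [m.unmasked().to_numpy() for m in maps]
    total_spots = int(sum(b.shape[0] for b in blocks))
    if total_spots < 3:
        raise ValueError(f"need at least 3 unmasked spots, got {total_spots}")

    K = len(states)
    if aggregation == "pooled":
        R = _pearson_matrix(np.vstack(blocks))
    else:
        num = np.zeros((K, K))
        wsum = np.zeros((K, K))
        for m, b in zip(maps, blocks):
            if b.shape[0] < 3:
                warnings.warn(
                    f"section {m.section_id!r} has fewer than 3 unmasked spots; skipped",
                    stacklevel=2,
                )
                continue
            r = _pearson_matrix(b)
            ok = np.isfinite(r)
            num[ok] += b.shape[0] * r[ok]
            wsum[ok] += b.shape[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            R = num / wsum
        R[wsum == 0] = np.nan
    if np.isnan(R).any():
        warnings.warn("zero-variance states produced missing scores", stacklevel=2)

    scores = pd.DataFrame(R, index=pd.Index(states, name="state"), columns=states)
    return CoDetectionMatrix(
        scores=scores,
        n_spots_used=total_spots,
        sections_used=[m.section_id for m in maps],
        aggregation=aggregation,
    )


def niche_graph(matrix: CoDetectionMatrix, threshold: float = DEFAULT_THRESHOLD) -> nx.Graph:
    """Threshold the score matrix into the niche network.

    An edge joins two states iff their score is strictly greater than the
    threshold; missing scores never create edges. Node attribute
    ``n_codetected`` records each state's degree, the number of co-detected
    partner states (used as circle size when drawing the network).
    """
    G = nx.Graph(threshold=threshold)
    states = matrix.states
    G.add_nodes_from(states)
    for i in range(len(states)):
        for j in range(i + 1, len(states)):
            score = matrix.scores.iat[i, j]
            if np.isfinite(score) and score > threshold:
                G.add_edge(states[i], states[j], score=float(score))
    nx.set_node_attributes(G, dict(G.degree()), "n_codetected")
    return G


def assign_age_groups(
    sections, bounds: tuple[tuple[float, float], ...] = DEFAULT_AGE_BOUNDS
) -> AgeGroupPartition:
    """Assign each section to the developmental age group containing its PCW.

    ``sections`` is any iterable of objects with ``section_id`` and ``pcw``
    attributes (SpatialSection or ProportionMap). Gaps between printed
    intervals are closed by extending each interval up to the next one's
    start, so e.g. PCW 6.5 falls in the 5.5-6 group when the next interval
    starts at 7. PCW outside the overall range is an error.
    """
    bounds = tuple(tuple(b) for b in bounds)
    starts = [b[0] for b in bounds]
    if starts != sorted(starts) or any(lo > hi for lo, hi in bounds):
        raise ValueError("bounds must be ordered, non-overlapping intervals")
    lo_all, hi_all = bounds[0][0], bounds[-1][1]
    assignment: dict[str, int] = {}
    for sec in sections:
        pcw = float(sec.pcw)
        if pcw < lo_all or pcw > hi_all:
            raise ValueError(
                f"section {sec.section_id!r} has PCW {pcw} outside "
                f"[{lo_all}, {hi_all}]"
            )
        group = len(bounds) - 1
        for g in range(len(bounds) - 1):
            if pcw < bounds[g + 1][0]:  # gap-closing: interval extends to next start
                group = g
                break
        assignment[sec.section_id] = group
    return AgeGroupPartition(bounds=bounds, assignment=assignment)


def _edge_set(matrix: CoDetectionMatrix, threshold: float) -> set[frozenset]:
    return {frozenset(e) for e in niche_graph(matrix, threshold).edges}


def group_stability(
    maps: list[ProportionMap],
    partition: AgeGroupPartition,
    threshold: float = DEFAULT_THRESHOLD,
    aggregation: str = "per_section_weighted",
) -> tuple[dict[int, CoDetectionMatrix], pd.DataFrame]:
    """Per-age-group co-detection matrices and a group x group stability report.

    For every group pair the report gives the Pearson correlation between
    the groups' upper-triangle score vectors (missing entries excluded
    pairwise) and the Jaccard index of their thresholded edge sets (defined
    as 1 when both sets are empty). Self-comparisons are exactly 1.
    """
    by_group: dict[int, list[ProportionMap]] = {g: [] for g in range(partition.n_groups)}
    for m in maps:
        if m.section_id not in partition.assignment:
            raise ValueError(f"section {m.section_id!r} missing from the partition")
        by_group[partition.assignment[m.section_id]].append(m)
    empty = [g for g, ms in by_group.items() if not ms]
    if empty:
        labels = partition.labels()
        raise ValueError(
            "age group(s) with no sections: " + ", ".join(labels[g] for g in empty)
        )

    matrices = {
        g: codetection_matrix(ms, aggregation=aggregation) for g, ms in by_group.items()
    }
    triangles = {g: m.upper_triangle() for g, m in matrices.items()}
    edges = {g: _edge_set(m, threshold) for g, m in matrices.items()}

    rows = []
    labels = partition.labels()
    for a in range(partition.n_groups):
        for b in range(partition.n_groups):
            if a == b:
                corr, jac = 1.0, 1.0
            else:
                ta, tb = triangles[a], triangles[b]
                ok = ta.notna() & tb.notna()
                if ok.sum() < 2:
                    corr = float("nan")
                else:
                    corr = float(np.corrcoef(ta[ok], tb[ok])[0, 1])
                ea, eb = edges[a], edges[b]
                jac = 1.0 if not (ea | eb) else len(ea & eb) / len(ea | eb)
            rows.append(
                {
                    "group_a": labels[a],
                    "group_b": labels[b],
                    "score_correlation": corr,
                    "edge_jaccard": jac,
                }
            )
    return matrices, pd.DataFrame(rows)
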
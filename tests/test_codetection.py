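"""Co-detection scores, the thresholded niche graph, and age-group stability."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioniche.codetection import (
    CoDetectionMatrix,
    assign_age_groups,
    codetection_matrix,
    group_stability,
    niche_graph,
)
from cardioniche.deconvolution import ProportionMap, fit_proportions
from cardioniche.profiles import profiles_from_anndata
from cardioniche.synthetic import SyntheticConfig, generate_reference, generate_sections

from conftest import brute_force_pearson


def _map_from(P: np.ndarray, states=None, section_id="sec", pcw=8.0, mask=None):
    states = states or [f"s{i}" for i in range(P.shape[1])]
    if mask is None:
        mask = np.zeros(P.shape[0], dtype=bool)
    return ProportionMap(
        proportions=pd.DataFrame(
            P, index=[f"spot{i}" for i in range(P.shape[0])], columns=states
        ),
        section_id=section_id,
        coords=np.zeros((P.shape[0], 2)),
        mask=mask,
        pcw=pcw,
    )


def _matrix_from_scores(S: np.ndarray, states=None) -> CoDetectionMatrix:
    states = states or [f"s{i}" for i in range(S.shape[0])]
    return CoDetectionMatrix(
        scores=pd.DataFrame(S, index=states, columns=states),
        n_spots_used=10,
        sections_used=["sec"],
        aggregation="pooled",
    )


class TestCodetectionMatrix:
    def test_identical_columns_score_one(self):
        p = np.array([0.3, 0.5, 0.2, 0.4])
        P = np.column_stack([p, p, 1 - 2 * p + 0.5])
        P = P / P.sum(axis=1, keepdims=True)
        # columns 0 and 1 stay proportional, hence perfectly correlated
        m = codetection_matrix([_map_from(P)], aggregation="pooled")
        assert m.scores.iat[0, 1] == pytest.approx(1.0)

    def test_compositional_complement_scores_minus_one(self):
        p = np.array([0.1, 0.4, 0.7, 0.2])
        P = np.column_stack([p, 1 - p])
        m = codetection_matrix([_map_from(P)], aggregation="pooled")
        assert m.scores.iat[0, 1] == pytest.approx(-1.0)

    def test_four_spot_toy_matches_frozen_hand_value(self):
        a = np.array([0.9, 0.8, 0.1, 0.2])
        b = np.array([0.8, 0.9, 0.2, 0.1])
        # hand Pearson: centered products sum 0.48, both variances 0.5 -> r = 0.96
        assert brute_force_pearson(a, b) == pytest.approx(0.96)
        # halve both columns (Pearson is scale-invariant) and pad to the simplex
        P = np.column_stack([a / 2, b / 2, 1 - (a + b) / 2])
        m = codetection_matrix([_map_from(P)], aggregation="pooled")
        assert m.scores.iat[0, 1] == pytest.approx(0.96, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 40), st.integers(2, 6))
    def test_pooled_matches_brute_force_pearson(self, seed, n_spots, n_states):
        rng = np.random.default_rng(seed)
        P = rng.dirichlet(np.ones(n_states), size=n_spots)
        m = codetection_matrix([_map_from(P)], aggregation="pooled")
        for i, j in itertools.combinations(range(n_states), 2):
            expect = brute_force_pearson(P[:, i], P[:, j])
            got = m.scores.iat[i, j]
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-10)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(3)
        P = rng.dirichlet(np.ones(5), size=100)
        m = codetection_matrix([_map_from(P)], aggregation="pooled")
        S = m.scores.to_numpy()
        assert np.allclose(S, S.T, atol=1e-12)
        assert np.nanmin(S) >= -1 and np.nanmax(S) <= 1
        assert np.allclose(np.diag(S), 1.0)

    def test_per_section_weighted_is_spotcount_weighted_average(self):
        rng = np.random.default_rng(4)
        P1 = rng.dirichlet(np.ones(3), size=10)
        P2 = rng.dirichlet(np.ones(3), size=30)
        m = codetection_matrix(
            [_map_from(P1, section_id="a"), _map_from(P2, section_id="b")],
            aggregation="per_section_weighted",
        )
        r1 = brute_force_pearson(P1[:, 0], P1[:, 1])
        r2 = brute_force_pearson(P2[:, 0], P2[:, 1])
        assert m.scores.iat[0, 1] == pytest.approx((10 * r1 + 30 * r2) / 40, abs=1e-10)

    def test_zero_variance_state_is_missing_not_zero(self):
        P = np.column_stack(
            [np.full(5, 0.5), np.linspace(0.1, 0.4, 5), 0.5 - np.linspace(0.1, 0.4, 5)]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            m = codetection_matrix([_map_from(P)], aggregation="pooled")
        assert np.isnan(m.scores.iat[0, 1])

    def test_masked_spot_changes_nothing(self):
        rng = np.random.default_rng(5)
        P = rng.dirichlet(np.ones(3), size=20)
        m1 = codetection_matrix([_map_from(P)], aggregation="pooled")
        extra = np.vstack([P, np.zeros(3)])
        mask = np.zeros(21, dtype=bool)
        mask[-1] = True
        pm = _map_from(extra, mask=mask)
        m2 = codetection_matrix([pm], aggregation="pooled")
        assert np.allclose(m1.scores, m2.scores, equal_nan=True)

    def test_fewer_than_three_spots_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            codetection_matrix([_map_from(np.array([[0.5, 0.5], [0.4, 0.6]]))])

    def test_mismatched_state_sets_rejected(self):
        m1 = _map_from(np.random.default_rng(0).dirichlet(np.ones(2), 5), states=["a", "b"])
        m2 = _map_from(np.random.default_rng(0).dirichlet(np.ones(2), 5), states=["a", "c"])
        with pytest.raises(ValueError, match="state sets differ"):
            codetection_matrix([m1, m2])

    def test_state_relabeling_permutes_matrix(self):
        rng = np.random.default_rng(6)
        P = rng.dirichlet(np.ones(4), size=30)
        perm = [2, 0, 3, 1]
        m1 = codetection_matrix([_map_from(P)], aggregation="pooled")
        m2 = codetection_matrix(
            [_map_from(P[:, perm], states=[f"s{i}" for i in perm])], aggregation="pooled"
        )
        reordered = m2.scores.loc[m1.states, m1.states]
        assert np.allclose(m1.scores, reordered, atol=1e-12)


class TestNicheGraph:
    def test_score_exactly_at_threshold_is_no_edge(self):
        S = np.array([[1.0, 0.07], [0.07, 1.0]])
        G = niche_graph(_matrix_from_scores(S), threshold=0.07)
        assert G.number_of_edges() == 0

    def test_all_zero_offdiagonal_gives_empty_graph(self):
        S = np.eye(4)
        G = niche_graph(_matrix_from_scores(S))
        assert G.number_of_edges() == 0
        assert all(d == 0 for _, d in G.degree())

    def test_edge_set_matches_brute_force_scan(self):
        vals = {(0, 1): 0.10, (0, 2): 0.05, (0, 3): 0.071, (1, 2): 0.069, (1, 3): -0.2, (2, 3): 0.3}
        S = np.eye(4)
        for (i, j), v in vals.items():
            S[i, j] = S[j, i] = v
        m = _matrix_from_scores(S)
        G = niche_graph(m, threshold=0.07)
        brute = {
            frozenset((f"s{i}", f"s{j}")) for (i, j), v in vals.items() if v > 0.07
        }
        assert {frozenset(e) for e in G.edges} == brute
        assert G.number_of_edges() == 3

    def test_missing_scores_never_create_edges(self):
        S = np.array([[1.0, np.nan], [np.nan, 1.0]])
        G = niche_graph(_matrix_from_scores(S), threshold=-2)
        assert G.number_of_edges() == 0

    def test_degree_attribute_counts_codetected_states(self):
        S = np.eye(3)
        S[0, 1] = S[1, 0] = 0.5
        S[0, 2] = S[2, 0] = 0.5
        G = niche_graph(_matrix_from_scores(S))
        assert G.nodes["s0"]["n_codetected"] == 2
        assert G.nodes["s1"]["n_codetected"] == 1


class TestNicheRecovery:
    def test_planted_niches_recovered_from_codetection(self):
        """3 block niches x 2 states: within-niche scores exceed cross-niche ones,
        and at low noise the graph components equal the planted partition."""
        # moderate noise: Poisson counts, finite Dirichlet concentration
        cfg = SyntheticConfig(seed=2)
        adata, _ = generate_reference(cfg)
        prof = profiles_from_anndata(adata)
        sections, _ = generate_sections(cfg)
        maps = [fit_proportions(s, prof) for s in sections]
        S = codetection_matrix(maps).scores
        within_pairs = [(0, 3), (1, 4), (2, 5)]
        within = [S.iat[i, j] for i, j in within_pairs]
        cross = [
            S.iat[i, j]
            for i, j in itertools.combinations(range(6), 2)
            if (i, j) not in within_pairs
        ]
        assert min(within) > max(cross)

        # low noise: noise-free counts, degenerate Dirichlet
        cfg_low = SyntheticConfig(seed=2, count_noise="none", fixed_mixture=True)
        adata_low, _ = generate_reference(cfg_low)
        prof_low = profiles_from_anndata(adata_low)
        sections_low, truth = generate_sections(cfg_low)
        maps_low = [fit_proportions(s, prof_low) for s in sections_low]
        G = niche_graph(codetection_matrix(maps_low))
        comps = sorted(sorted(c) for c in nx.connected_components(G))
        assert comps == [
            ["state_0", "state_3"],
            ["state_1", "state_4"],
            ["state_2", "state_5"],
        ]


class TestAgeGroups:
    @pytest.mark.parametrize(
        "pcw,group", [(8.0, 1), (9.0, 2), (6.5, 0), (5.5, 0), (14.0, 2), (7.0, 1)]
    )
    def test_assignment_with_gap_closing(self, pcw, group):
        sec = type("S", (), {"section_id": "x", "pcw": pcw})()
        part = assign_age_groups([sec])
        assert part.assignment["x"] == group

    def test_out_of_range_pcw_rejected(self):
        sec = type("S", (), {"section_id": "x", "pcw": 15.0})()
        with pytest.raises(ValueError, match="outside"):
            assign_age_groups([sec])

    def test_every_section_assigned_once(self):
        secs = [
            type("S", (), {"section_id": f"s{i}", "pcw": p})()
            for i, p in enumerate([5.5, 6.5, 8.0, 10.0, 13.9])
        ]
        part = assign_age_groups(secs)
        assert sorted(part.assignment) == [f"s{i}" for i in range(5)]


class TestGroupStability:
    @staticmethod
    def _maps_two_groups(seed=31):
        cfg = SyntheticConfig(
            seed=seed,
            n_sections=4,
            pcw_per_section=[5.5, 5.7, 12.5, 13.0],
        )
        adata, _ = generate_reference(cfg)
        prof = profiles_from_anndata(adata)
        sections, _ = generate_sections(cfg)
        maps = [fit_proportions(s, prof) for s in sections]
        partition = assign_age_groups(maps, bounds=((5.5, 6.0), (9.0, 14.0)))
        return maps, partition

    def test_shared_truth_groups_are_stable(self):
        maps, partition = self._maps_two_groups()
        matrices, report = group_stability(maps, partition)
        cross = report[(report["group_a"] == "5.5-6") & (report["group_b"] == "9-14")]
        assert cross["score_correlation"].iloc[0] >= 0.9
        assert cross["edge_jaccard"].iloc[0] >= 0.8

    def test_self_comparison_is_exactly_one(self):
        maps, partition = self._maps_two_groups()
        _, report = group_stability(maps, partition)
        diag = report[report["group_a"] == report["group_b"]]
        assert (diag["score_correlation"] == 1.0).all()
        assert (diag["edge_jaccard"] == 1.0).all()

    def test_disjoint_edge_sets_have_jaccard_zero(self):
        # construct maps whose groups correlate different state pairs
        n = 30
        t = np.linspace(0, 1, n)
        g1 = np.column_stack([t, t, 1 - 2 * t + 1.0]) / (2.0)
        rng = np.random.default_rng(0)
        g2 = np.column_stack([t, t[::-1], np.full(n, 1.0)])
        g2 = g2 / g2.sum(axis=1, keepdims=True)
        maps = [
            _map_from(g1 / g1.sum(axis=1, keepdims=True), section_id="a", pcw=5.5),
            _map_from(g2, section_id="b", pcw=13.0),
        ]
        partition = assign_age_groups(maps, bounds=((5.5, 6.0), (9.0, 14.0)))
        _, report = group_stability(maps, partition, threshold=0.07)
        cross = report[(report["group_a"] == "5.5-6") & (report["group_b"] == "9-14")]
        assert cross["edge_jaccard"].iloc[0] == 0.0

    def test_empty_group_named_in_error(self):
        maps, _ = self._maps_two_groups()
        from cardioniche.codetection import AgeGroupPartition

        partition = AgeGroupPartition(
            bounds=((5.5, 6.0), (7.0, 8.0), (9.0, 14.0)),
            assignment={m.section_id: 0 for m in maps},
        )
        with pytest.raises(ValueError, match="7-8"):
            group_stability(maps, partition)
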
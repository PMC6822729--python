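"""Triad classification, censuses, motif tests, chi-squared machinery."""

from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pytest
from scipy.stats import binom

import strepnet
from strepnet.triad_motifs import (
    N_TRIADS,
    TRIAD_NAMES,
    TriadCensus,
    classify_triad,
    cross_network_chisq,
    gof_chisq,
    monte_carlo_gof_p,
    motif_tests,
    per_triad_cross_network_tests,
    triad_census,
)
from strepnet.null_models import NullEnsembleSummary

from conftest import net_from_edges, random_network

PAIRS = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]


def edges_of_code(code):
    return [PAIRS[k] for k in range(6) if code & (1 << k)]


def iso_groups_by_brute_force():
    """Partition all 64 labeled 3-node digraphs into isomorphism classes.

    Pure permutation argument, independent of the package's tricode tables.
    """
    groups = {}
    for code in range(64):
        edges = edges_of_code(code)
        canon = min(
            tuple(sorted((p[u], p[v]) for u, v in edges))
            for p in permutations(range(3))
        )
        groups.setdefault(canon, []).append(code)
    return list(groups.values())


class TestClassifyTriad:
    def test_anchor_cases(self):
        assert classify_triad([]) == 1  # empty triad
        assert classify_triad([(0, 1)]) == 2
        assert classify_triad([(0, 1), (1, 0)]) == 3
        assert classify_triad([("A", "B"), ("A", "C")], nodes="ABC") == 4  # out-star
        assert classify_triad([(0, 1), (1, 2), (2, 0)]) == 10  # rock-paper-scissors
        assert classify_triad(PAIRS) == 16  # complete

    def test_exhaustive_isomorphism_oracle(self):
        """classify is constant on isomorphism classes and separates all 16."""
        groups = iso_groups_by_brute_force()
        assert len(groups) == 16
        seen = set()
        for group in groups:
            labels = {classify_triad(edges_of_code(code)) for code in group}
            assert len(labels) == 1
            seen |= labels
        assert seen == set(range(1, 17))

    def test_label_order_invariance(self):
        edges = [("x", "y"), ("y", "z"), ("x", "z")]
        classes = {
            classify_triad([(p[u], p[v]) for u, v in
                            [("x", "y"), ("y", "z"), ("x", "z")]], nodes="xyz")
            for p in [dict(zip("xyz", perm)) for perm in permutations("xyz")]
        }
        assert classes == {9}  # transitive triangle, 030T

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            classify_triad([(0, 0)])


class TestTriadCensus:
    def test_empty_graph(self):
        net = net_from_edges([], "abcde")
        counts = triad_census(net).counts
        assert counts[0] == 10 and counts[1:].sum() == 0

    def test_too_small_graph_rejected(self):
        with pytest.raises(ValueError):
            triad_census(net_from_edges([("a", "b")], "ab"))

    def test_census_totals_and_edge_identity(self, rng):
        for _ in range(40):
            net = random_network(rng, n_min=3, n_max=9)
            n, m = net.n_nodes, net.n_edges
            census = triad_census(net)
            assert census.total == n * (n - 1) * (n - 2) // 6
            from strepnet.triad_motifs import EDGE_COUNT_OF_CLASS

            assert (EDGE_COUNT_OF_CLASS * census.counts).sum() == m * (n - 2)

    def test_matches_networkx_census(self, rng):
        for _ in range(30):
            net = random_network(rng, n_min=4, n_max=8)
            nxc = nx.triadic_census(net.to_networkx())
            want = np.array([nxc[name] for name in TRIAD_NAMES])
            assert (triad_census(net).counts == want).all()

    def test_matches_per_triple_classification(self, rng):
        net = random_network(rng, n_min=6, n_max=6)
        adj = net.adjacency
        counts = np.zeros(16, dtype=int)
        for triple in combinations(range(6), 3):
            edges = [(u, v) for u in triple for v in triple
                     if u != v and adj[u, v]]
            counts[classify_triad(edges, nodes=triple) - 1] += 1
        assert (triad_census(net).counts == counts).all()


def _summary_from(means, sds, model="degree"):
    s = NullEnsembleSummary(model=model, n_reps=1000, seed=0)
    s.means["triad_census"] = np.asarray(means, dtype=float)
    s.sds["triad_census"] = np.asarray(sds, dtype=float)
    return s


class TestMotifTests:
    def test_census_equal_to_null_means_flags_nothing(self):
        means = np.arange(1.0, 17.0)
        census = TriadCensus(counts=means.astype(int), n_nodes=10)
        out = motif_tests(census, _summary_from(means, np.ones(16)))
        assert (out["z"] == 0).all()
        assert not out["motif"].any()
        assert (out["p_fdr"] >= out["p"]).all()

    def test_bh_adjustment_matches_hand_stepup(self):
        # plant known raw p-values via a degenerate null: sd=1, mean offset = z
        from scipy.stats import norm

        p_raw = np.array([0.001, 0.002, 0.01, 0.02, 0.04, 0.05, 0.1, 0.2,
                          0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.85, 0.9])
        z = norm.isf(p_raw / 2)
        census = TriadCensus(counts=np.zeros(16, int), n_nodes=10)
        out = motif_tests(census, _summary_from(-z, np.ones(16)))
        # hand step-up: p_(i) * n/i, cumulative min from the largest
        order = np.argsort(p_raw)
        stepped = p_raw[order] * 16 / np.arange(1, 17)
        hand = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(16)
        expected[order] = np.minimum(hand, 1)
        assert out["p"].to_numpy() == pytest.approx(p_raw, rel=1e-6)
        assert out["p_fdr"].to_numpy() == pytest.approx(expected, rel=1e-6)

    def test_detects_strong_excess(self):
        means = np.full(16, 10.0)
        census_counts = np.full(16, 10, dtype=int)
        census_counts[9] = 40  # strong excess of the 3-cycle class
        out = motif_tests(TriadCensus(counts=census_counts, n_nodes=12),
                          _summary_from(means, np.full(16, 2.0)))
        assert bool(out.loc[out["triad"] == 10, "motif"].iloc[0])


class TestChiSquared:
    def test_gof_zero_iff_equal(self):
        e = np.arange(1.0, 17.0)
        assert gof_chisq(e, e) == 0.0
        o = e.copy()
        o[3] += 5
        assert gof_chisq(o, e) > 0

    def test_gof_hand_computation(self):
        assert gof_chisq([10, 0], [5, 5]) == pytest.approx(10.0)

    def test_gof_zero_expected_with_observed_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            gof_chisq([1, 1], [1, 0])

    def test_monte_carlo_p_bounds_and_null_case(self, rng):
        e = np.array([50.0, 30.0, 20.0])
        stat, p = monte_carlo_gof_p([50, 30, 20], e, n_sim=500, rng=rng)
        assert stat == 0.0
        assert p == 1.0
        _, p2 = monte_carlo_gof_p([90, 5, 5], e, n_sim=500, rng=rng)
        assert 1 / 501 <= p2 < 0.01

    def test_monte_carlo_p_matches_exact_binomial_tail(self, rng):
        # 2 categories, n=20, fair expected: exact tail by enumeration
        o = np.array([15, 5])
        e = np.array([10.0, 10.0])
        stat, p_mc = monte_carlo_gof_p(o, e, n_sim=4000, rng=rng)
        ks = np.arange(21)
        stats = (ks - 10) ** 2 / 10 + (20 - ks - 10) ** 2 / 10
        exact = binom.pmf(ks, 20, 0.5)[stats >= stat].sum()
        assert p_mc == pytest.approx(exact, abs=0.02)

    def test_cross_network_identical_censuses_give_zero(self, rng):
        counts = np.arange(1, 17)
        censuses = {
            k: TriadCensus(counts=counts, n_nodes=10, community_id=k) for k in "AB"
        }
        out = cross_network_chisq(censuses, n_sim=200, rng=rng)
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_cross_network_hand_2x2(self, rng):
        a = np.zeros(16, int)
        b = np.zeros(16, int)
        a[0], b[1] = 10, 10
        censuses = {"A": TriadCensus(counts=a, n_nodes=10),
                    "B": TriadCensus(counts=b, n_nodes=10)}
        out = cross_network_chisq(censuses, n_sim=500, rng=rng)
        assert out["statistic"] == pytest.approx(20.0)
        assert out["p"] < 0.05
        assert len(out["dropped_triads"]) == 14

    def test_per_triad_tests(self, rng):
        counts = np.zeros(16, int)
        counts[0] = 30
        equal = {k: TriadCensus(counts=counts, n_nodes=10) for k in "ABC"}
        out = per_triad_cross_network_tests(equal, n_sim=300, rng=rng)
        row0 = out[out["triad"] == 1].iloc[0]
        assert row0["statistic"] == pytest.approx(0.0)
        assert out[out["triad"] == 2]["skipped"].iloc[0]  # absent everywhere

    def test_per_triad_single_class_vs_direct_formula(self, rng):
        c1 = np.zeros(16, int); c1[0] = 12
        c2 = np.zeros(16, int); c2[0] = 4
        censuses = {"A": TriadCensus(counts=c1, n_nodes=10),
                    "B": TriadCensus(counts=c2, n_nodes=10)}
        out = per_triad_cross_network_tests(censuses, n_sim=300, rng=rng)
        # totals 12 and 4 -> expected split (12, 4) of the 16 class-1 triads
        # observed equals expected -> statistic 0
        assert out[out["triad"] == 1]["statistic"].iloc[0] == pytest.approx(0.0)


class TestPlantedMotifs:
    def test_planted_class_counts(self, rng):
        base = strepnet.InhibitionMatrix(
            labels=tuple(map(str, range(9))), cells=np.zeros((9, 9), int)
        )
        planted = strepnet.plant_triads(base, strepnet.PlantSpec(10, 2), rng)
        census = triad_census(strepnet.build_network(planted))
        assert census.counts[9] == 2
        planted16 = strepnet.plant_triads(base, strepnet.PlantSpec(16, 1), rng)
        assert planted16.n_edges == 6
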
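"""Orbit enumeration, node signatures, Shannon diversity, ANOVA, clustering."""

import math

import numpy as np
import pandas as pd
import pytest

import strepnet
from strepnet.orbit_signatures import (
    ORBITS,
    cluster_signatures,
    community_anova,
    linkage_to_newick,
    node_orbit_census,
    node_shannon,
    orbit_table,
    shannon_by_node,
    signature_heatmap_matrix,
)
from strepnet.triad_motifs import triad_census

from conftest import net_from_edges, random_network


class TestOrbitTable:
    def test_thirty_orbits_across_connected_classes(self):
        table = orbit_table()
        assert len(table) == 30
        assert set(table["triad"]) == set(range(4, 17))

    def test_three_cycle_has_single_orbit(self):
        table = orbit_table()
        t10 = table[table["triad"] == 10]
        assert len(t10) == 1
        assert (t10["out_degree"].iloc[0], t10["in_degree"].iloc[0]) == (1, 1)
        assert t10["n_positions"].iloc[0] == 3

    def test_orbit_sizes_sum_to_three_per_class(self):
        table = orbit_table()
        assert (table.groupby("triad")["n_positions"].sum() == 3).all()

    def test_expected_multiplicities(self):
        counts = orbit_table().groupby("triad").size()
        assert list(counts.loc[range(4, 17)]) == [2, 2, 3, 3, 3, 3, 1, 2, 2, 2, 3, 3, 1]


class TestNodeOrbitCensus:
    def test_out_star_positions(self):
        net = net_from_edges([("A", "B"), ("A", "C")], "ABC")
        sig = node_orbit_census(net)
        assert sig.loc["A", "t4.2.0"] == 1
        assert sig.loc["B", "t4.0.1"] == 1 and sig.loc["C", "t4.0.1"] == 1
        assert sig.to_numpy().sum() == 3

    def test_complete_mutual_triangle(self, complete_mutual_3):
        sig = node_orbit_census(complete_mutual_3)
        assert (sig["t16.2.2"] == 1).all()
        assert sig.to_numpy().sum() == 3

    def test_consistency_with_triad_census(self, rng):
        """Orbit totals are the census weighted by orbit multiplicities."""
        for _ in range(25):
            net = random_network(rng, n_min=4, n_max=7)
            sig = node_orbit_census(net)
            census = triad_census(net).counts
            assert sig.to_numpy().sum() == 3 * census[3:].sum()
            for orbit in ORBITS:
                assert (
                    sig[orbit.orbit_id].sum()
                    == orbit.n_positions * census[orbit.triad_index - 1]
                )


class TestSignaturesAndDiversity:
    def test_heatmap_sqrt_values(self):
        sig = pd.DataFrame([[1, 3] + [0] * 28], index=["x"],
                           columns=[o.orbit_id for o in ORBITS])
        mat = signature_heatmap_matrix(sig)
        assert mat.iloc[0, 0] == pytest.approx(0.5)
        assert mat.iloc[0, 1] == pytest.approx(math.sqrt(0.75))
        assert (mat.iloc[0] ** 2).sum() == pytest.approx(1.0)

    def test_zero_rows_stay_zero(self):
        sig = pd.DataFrame(np.zeros((1, 30)), index=["x"],
                           columns=[o.orbit_id for o in ORBITS])
        assert (signature_heatmap_matrix(sig).to_numpy() == 0).all()

    def test_shannon_single_orbit_is_zero(self):
        v = np.zeros(30)
        v[4] = 7
        assert node_shannon(v) == 0.0

    def test_shannon_uniform_closed_form(self):
        v = np.zeros(30)
        v[:4] = 5
        assert node_shannon(v) == pytest.approx(math.log(4))

    def test_shannon_bounded_by_log_orbits(self, rng):
        for _ in range(10):
            net = random_network(rng, n_min=6, n_max=9)
            for h in shannon_by_node(node_orbit_census(net)):
                assert 0 <= h <= math.log(30) + 1e-12

    def test_anova_equal_means_give_zero_f(self):
        out = community_anova({"A": [1.0, 2.0, 3.0], "B": [2.0, 1.0, 3.0]})
        assert out["F"] == pytest.approx(0.0)

    def test_anova_matches_hand_sums_of_squares(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 6.0, 8.0]
        out = community_anova({"A": a, "B": b})
        grand = np.mean(a + b)
        ss_between = 3 * ((np.mean(a) - grand) ** 2 + (np.mean(b) - grand) ** 2)
        ss_within = sum((x - np.mean(a)) ** 2 for x in a) + sum(
            (x - np.mean(b)) ** 2 for x in b
        )
        f_hand = (ss_between / 1) / (ss_within / 4)
        assert out["F"] == pytest.approx(f_hand)

    def test_anova_needs_replication(self):
        with pytest.raises(ValueError):
            community_anova({"A": [1.0], "B": [2.0, 3.0]})


class TestClustering:
    def test_identical_vectors_merge_first_at_zero_distance(self):
        base = np.zeros(30)
        base[0], base[5] = 3, 1
        other = np.zeros(30)
        other[10], other[12] = 2, 2
        sig = pd.DataFrame(
            [base, base, other], index=["x1", "x2", "y"],
            columns=[o.orbit_id for o in ORBITS],
        )
        out = cluster_signatures(sig)
        first_merge = out["linkage"][0]
        merged = {out["nodes"][int(first_merge[0])], out["nodes"][int(first_merge[1])]}
        assert merged == {"x1", "x2"}
        assert first_merge[2] == pytest.approx(0.0, abs=1e-12)

    def test_nonparticipating_nodes_excluded(self):
        a = np.zeros(30); a[0] = 1; a[3] = 2
        b = np.zeros(30); b[7] = 2; b[2] = 1
        zero = np.zeros(30)
        sig = pd.DataFrame([a, b, zero], index=["a", "b", "z"],
                           columns=[o.orbit_id for o in ORBITS])
        out = cluster_signatures(sig)
        assert out["excluded"] == ["z"]
        assert out["nodes"] == ["a", "b"]

    def test_planted_groups_recovered(self, rng):
        """Three planted participation patterns recovered at k=3 (Rand > 0.9)."""
        from scipy.special import comb

        patterns = np.zeros((3, 30))
        patterns[0, [0, 1, 4]] = (5, 3, 2)
        patterns[1, [10, 12, 15]] = (4, 4, 2)
        patterns[2, [20, 25, 29]] = (6, 2, 2)
        rows, truth = [], []
        for g in range(3):
            for _ in range(8):
                noisy = patterns[g] + rng.poisson(0.3, size=30)
                rows.append(noisy)
                truth.append(g)
        sig = pd.DataFrame(rows, index=[f"n{i}" for i in range(24)],
                           columns=[o.orbit_id for o in ORBITS])
        out = cluster_signatures(sig, k=3)
        labels = out["clusters"].to_numpy()
        truth = np.array(truth)
        # Rand index by pair agreement
        agree = total = 0
        for i in range(24):
            for j in range(i + 1, 24):
                total += 1
                agree += (labels[i] == labels[j]) == (truth[i] == truth[j])
        assert agree / total > 0.9

    def test_newick_round_trip_leaf_names(self):
        a = np.zeros(30); a[0] = 1; a[2] = 3
        b = np.zeros(30); b[5] = 2; b[1] = 1
        c = np.zeros(30); c[8] = 1; c[9] = 4
        sig = pd.DataFrame([a, b, c], index=["i1", "i2", "i3"],
                           columns=[o.orbit_id for o in ORBITS])
        out = cluster_signatures(sig)
        newick = linkage_to_newick(out["linkage"], out["nodes"])
        assert newick.endswith(";")
        for name in ("i1", "i2", "i3"):
            assert name in newick
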
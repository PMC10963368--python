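"""Energy aggregation, hotspot classification, cumulative profiles,
KS comparison, and hotspot clustering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cotrans.datatypes import EnergyTable
from cotrans.energetics import (
    HotspotCluster,
    aggregate_replicates,
    classify_hotspots,
    cluster_energy_fraction,
    cumulative_profile,
    ks_compare,
    linear_clusters,
    spatial_clusters,
)
from cotrans.exceptions import ValidationError
from cotrans.synthetic import ToyComplexSpec, gen_toy_complex


def make_table(means, orf_length=None, n_rep=1):
    """Table whose replicate values all equal the given means."""
    means = np.asarray(means, dtype=float)
    table = EnergyTable(
        residue_index=np.arange(1, len(means) + 1),
        replicates=np.repeat(means[:, None], n_rep, axis=1),
        orf_length=orf_length,
    )
    return aggregate_replicates(table)


class TestAggregateReplicates:
    def test_identical_replicates(self):
        table = EnergyTable(residue_index=[1], replicates=[[-3.0, -3.0, -3.0]])
        aggregate_replicates(table)
        assert table.mean[0] == -3.0 and table.sd[0] == 0.0

    def test_two_replicates_hand_value(self):
        table = EnergyTable(residue_index=[1], replicates=[[-2.0, -4.0]])
        aggregate_replicates(table)
        assert table.mean[0] == pytest.approx(-3.0)
        assert table.sd[0] == pytest.approx(np.sqrt(2.0))

    def test_single_replicate_warns_with_zero_sd(self):
        table = EnergyTable(residue_index=[1, 2], replicates=[[-1.0], [2.0]])
        aggregate_replicates(table)
        assert table.single_replicate_warning
        assert np.all(table.sd == 0.0)

    @given(values=arrays(np.float64, (15, 4), elements=st.floats(-20, 20)))
    def test_matches_brute_force(self, values):
        table = EnergyTable(residue_index=np.arange(1, 16), replicates=values)
        aggregate_replicates(table)
        for i in range(15):
            row = values[i]
            assert table.mean[i] == pytest.approx(row.mean(), abs=1e-12)
            assert table.sd[i] == pytest.approx(row.std(ddof=1), abs=1e-12)


class TestClassifyHotspots:
    def test_strongly_favorable_residue_is_hotspot(self):
        table = make_table([-8.0, -0.5])
        assert classify_hotspots(table) == {1}

    def test_boundary_exactly_minus_two_excluded(self):
        table = make_table([-2.0, -2.0000001])
        assert classify_hotspots(table) == {2}  # strict <

    @given(means=arrays(np.float64, 30, elements=st.floats(-10, 10)))
    def test_matches_brute_force_filter(self, means):
        table = make_table(means)
        got = classify_hotspots(table, threshold=-2.0)
        brute = {i + 1 for i, m in enumerate(means) if m < -2.0}
        assert got == brute

    @given(means=arrays(np.float64, 20, elements=st.floats(-10, 2)))
    def test_monotone_in_threshold(self, means):
        table = make_table(means)
        loose = classify_hotspots(table, threshold=-1.0)
        tight = classify_hotspots(table, threshold=-4.0)
        assert tight <= loose


class TestCumulativeProfile:
    def test_uniform_contributions_linear(self):
        table = make_table([-1.0] * 10)
        prof = cumulative_profile(table)
        assert np.allclose(prof.magnitude, np.arange(1, 11) / 10)
        assert np.allclose(prof.signed, -np.arange(1, 11) / 10)
        assert prof.magnitude[-1] == pytest.approx(1.0)
        assert prof.signed_total == pytest.approx(-10.0)

    def test_single_contribution_is_step(self):
        means = np.zeros(8)
        means[4] = -3.0  # residue 5
        prof = cumulative_profile(make_table(means))
        assert np.allclose(prof.magnitude[:4], 0.0)
        assert np.allclose(prof.magnitude[4:], 1.0)

    def test_missing_residues_contribute_zero(self):
        table = EnergyTable(residue_index=[2, 4], replicates=[[-1.0], [-1.0]],
                            orf_length=6)
        aggregate_replicates(table)
        prof = cumulative_profile(table)
        assert np.allclose(prof.magnitude, [0, 0.5, 0.5, 1.0, 1.0, 1.0])

    def test_planted_cluster_accrues_its_fraction(self, clustered_table):
        table, truth = clustered_table
        prof = cumulative_profile(table)
        s, e = truth["cluster_spans"][0]
        accrued = prof.magnitude[e - 1] - prof.magnitude[s - 2]
        assert accrued >= 0.75  # cluster planted to carry most of the energy

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValidationError):
            cumulative_profile(make_table(np.zeros(5)))

    def test_decomposition_conservation(self, clustered_table):
        table, _ = clustered_table
        prof = cumulative_profile(table)
        assert prof.signed_total == pytest.approx(float(table.mean.sum()), abs=1e-9)


def brute_force_ks_d(pos_a, w_a, pos_b, w_b):
    """Sup over all sample points of the weighted CDF difference."""
    def cdf(pos, w, x):
        total = w.sum()
        return sum(wi for p, wi in zip(pos, w) if p <= x) / total

    d = 0.0
    for x in np.concatenate([pos_a, pos_b]):
        d = max(d, abs(cdf(pos_a, w_a, x) - cdf(pos_b, w_b, x)))
    return d


class TestKsCompare:
    def test_identical_profiles(self, clustered_table):
        table, _ = clustered_table
        prof = cumulative_profile(table)
        d, p = ks_compare(prof, prof)
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports_give_d_one(self):
        means_a = np.zeros(100)
        means_a[9] = -5.0  # all mass at position 0.1
        means_b = np.zeros(100)
        means_b[89] = -5.0  # all mass at position 0.9
        d, _ = ks_compare(cumulative_profile(make_table(means_a)),
                          cumulative_profile(make_table(means_b)))
        assert d == pytest.approx(1.0)

    @given(
        means_a=arrays(np.float64, 25, elements=st.floats(-5, 5)),
        means_b=arrays(np.float64, 25, elements=st.floats(-5, 5)),
    )
    def test_d_matches_brute_force_sup_scan(self, means_a, means_b):
        if np.abs(means_a).sum() == 0 or np.abs(means_b).sum() == 0:
            return
        prof_a = cumulative_profile(make_table(means_a))
        prof_b = cumulative_profile(make_table(means_b))
        d, _ = ks_compare(prof_a, prof_b)
        mask_a, mask_b = np.abs(means_a) > 0, np.abs(means_b) > 0
        brute = brute_force_ks_d(
            (np.arange(1, 26) / 25)[mask_a], np.abs(means_a)[mask_a],
            (np.arange(1, 26) / 25)[mask_b], np.abs(means_b)[mask_b],
        )
        assert d == pytest.approx(brute, abs=1e-12)

    def test_unweighted_mode_matches_scipy_on_unit_weights(self):
        rng = np.random.default_rng(8)
        means_a = np.where(rng.random(50) < 0.4, -1.0, 0.0)
        means_b = np.where(rng.random(50) < 0.4, -1.0, 0.0)
        if not means_a.any() or not means_b.any():
            pytest.skip("degenerate draw")
        prof_a = cumulative_profile(make_table(means_a))
        prof_b = cumulative_profile(make_table(means_b))
        d_w, _ = ks_compare(prof_a, prof_b, weighted=True)
        d_u, _ = ks_compare(prof_a, prof_b, weighted=False)
        # with all |energies| equal the two constructions coincide
        assert d_w == pytest.approx(d_u, abs=1e-12)


class TestLinearClusters:
    def test_two_anchor_hotspots_bridge_into_one_cluster(self):
        means = np.zeros(100)
        for r in (47, 50, 95):
            means[r - 1] = -5.0
        table = make_table(means)
        clusters = linear_clusters({47, 50, 95}, table, cluster_gap=45)
        assert len(clusters) == 1
        assert clusters[0].span == (47, 95)
        assert clusters[0].total_energy == pytest.approx(-15.0)

    def test_distant_hotspots_split(self):
        means = np.zeros(250)
        means[9] = means[199] = -4.0
        clusters = linear_clusters({10, 200}, make_table(means), cluster_gap=20)
        assert [c.span for c in clusters] == [(10, 10), (200, 200)]

    @given(
        hotspots=st.sets(st.integers(1, 60), max_size=15),
        gap=st.integers(1, 20),
    )
    def test_matches_transitive_closure_oracle(self, hotspots, gap):
        means = np.zeros(60)
        for r in hotspots:
            means[r - 1] = -3.0
        table = make_table(means)
        clusters = linear_clusters(hotspots, table, cluster_gap=gap)
        # brute force: grow groups until fixpoint
        groups = [{r} for r in hotspots]
        changed = True
        while changed:
            changed = False
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    if any(abs(a - b) <= gap for a in groups[i] for b in groups[j]):
                        groups[i] |= groups.pop(j)
                        changed = True
                        break
                if changed:
                    break
        got = {frozenset(c.members) for c in clusters}
        assert got == {frozenset(g) for g in groups}
        # clusters partition the hotspot set
        all_members = [m for c in clusters for m in c.members]
        assert sorted(all_members) == sorted(hotspots)


class TestSpatialClusters:
    def test_sequence_distant_spatial_neighbors_join(self):
        # residues 3 and 9 of chain A sit ~sequence-apart; force them close
        spec = ToyComplexSpec(
            n_residues_chain_a=12, n_residues_chain_b=4,
            interface_pairs=[(1, 1, 5.0)], fluctuation_amplitudes=0.0,
            n_frames=2,
        )
        structure, _ = gen_toy_complex(spec)
        ca = structure.ca_map("A")
        means = np.zeros(12)
        means[[2, 8]] = -5.0
        table = make_table(means)
        gap = float(np.linalg.norm(ca[3] - ca[9]))
        one = spatial_clusters({3, 9}, table, structure, "A",
                               spatial_cutoff=gap + 0.1)
        two = spatial_clusters({3, 9}, table, structure, "A",
                               spatial_cutoff=gap - 0.1)
        assert len(one) == 1 and sorted(one[0].members) == [3, 9]
        assert len(two) == 2

    @given(seed=st.integers(0, 200))
    def test_matches_brute_force_connected_components(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        coords = rng.uniform(0, 15, size=(n, 3))
        from cotrans.datatypes import Atom, Chain, ComplexStructure, Residue

        residues = [Residue(i + 1, "GLY", [Atom("CA", "C", coords[i])])
                    for i in range(n)]
        structure = ComplexStructure([Chain("A", residues)])
        table = make_table(np.full(n, -3.0))
        hotspots = set(range(1, n + 1))
        cutoff = 6.0
        clusters = spatial_clusters(hotspots, table, structure, "A", cutoff)
        # brute-force: union-find by pairwise distance
        groups = [{r} for r in hotspots]
        changed = True
        while changed:
            changed = False
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    if any(
                        np.linalg.norm(coords[a - 1] - coords[b - 1]) <= cutoff
                        for a in groups[i] for b in groups[j]
                    ):
                        groups[i] |= groups.pop(j)
                        changed = True
                        break
                if changed:
                    break
        assert {frozenset(c.members) for c in clusters} == \
            {frozenset(g) for g in groups}

    def test_hotspot_without_coordinates_rejected(self, toy_complex):
        _, structure, _ = toy_complex
        table = make_table(np.full(40, -3.0))
        with pytest.raises(ValidationError, match="without C"):
            spatial_clusters({35}, table, structure, "A", 8.0)


class TestClusterEnergyFraction:
    def test_cluster_of_everything_is_one(self):
        means = np.full(10, -2.5)
        table = make_table(means)
        cluster = HotspotCluster("L1", list(range(1, 11)), (1, 10),
                                 float(means.sum()), "linear")
        assert cluster_energy_fraction(cluster, table) == pytest.approx(1.0)

    def test_empty_cluster_is_zero(self):
        table = make_table([-1.0, -2.0])
        cluster = HotspotCluster("L1", [], (0, 0), 0.0, "linear")
        assert cluster_energy_fraction(cluster, table) == 0.0

    def test_planted_fraction_recovered(self, clustered_table):
        table, truth = clustered_table
        hotspots = classify_hotspots(table)
        clusters = linear_clusters(hotspots, table, cluster_gap=10)
        assert len(clusters) == 1
        frac = cluster_energy_fraction(clusters[0], table)
        # planted bookkeeping says the cluster carries all planted energy;
        # measured mass adds a noise floor over the 168 background residues
        assert truth["cluster_energy_fractions"][0] == pytest.approx(1.0)
        assert frac >= 0.75
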
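import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cocomo2 import (ChainSpec, build_topology, dilute_concentration,
                     find_clusters, radius_of_gyration)
from cocomo2.constants import AVOGADRO
from cocomo2.phase import (CsatEstimate, PhaseReport, StartConfig, build_start,
                           estimate_csat)

from reference import brute_rg, union_find_clusters


def toy_topology(params, n_chains=6, length=5):
    spec = ChainSpec(chain_id="t", sequence="G" * length, copies=n_chains)
    return build_topology([spec], params)


def report_from_counts(monomer_series, box, params, largest=10):
    """Synthetic PhaseReport with the given per-frame monomer counts."""
    assignments, largest_list, dil = [], [], []
    for m in monomer_series:
        labels = np.concatenate([np.zeros(largest, dtype=int),
                                 np.arange(1, m + 1)])
        assignments.append(labels)
        largest_list.append(largest)
        dil.append(dilute_concentration(labels, box))
    return PhaseReport(frame_steps=list(range(len(monomer_series))),
                       assignments=assignments,
                       largest_cluster=np.array(largest_list),
                       monomer_count=np.array(monomer_series),
                       dilute_uM=np.array(dil))


class TestClustering:
    def test_far_apart_chains_are_singletons(self, cocomo2_params):
        top = toy_topology(cocomo2_params, n_chains=4)
        coords = np.zeros((top.n_beads, 3))
        for k, sl in enumerate(top.chain_slices()):
            coords[sl] = [5.0 * k + 10.0, 10.0, 10.0]
        labels = find_clusters(coords, np.full(3, 40.0), top)
        assert len(np.unique(labels)) == 4

    def test_single_linkage_transitivity(self, cocomo2_params):
        # A touches B, B touches C, A far from C: one 3-chain cluster
        top = toy_topology(cocomo2_params, n_chains=3, length=2)
        coords = np.array([
            [2.0, 2.0, 2.0], [2.4, 2.0, 2.0],      # A
            [3.0, 2.0, 2.0], [3.4, 2.0, 2.0],      # B (0.6 from A tail)
            [4.0, 2.0, 2.0], [4.4, 2.0, 2.0],      # C (0.6 from B tail)
        ])
        labels = find_clusters(coords, np.full(3, 20.0), top)
        assert len(np.unique(labels)) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_union_find_oracle(self, cocomo2_params, seed):
        rng = np.random.default_rng(seed)
        top = toy_topology(cocomo2_params, n_chains=10, length=4)
        box = np.full(3, 8.0)
        coords = rng.random((top.n_beads, 3)) * 8.0
        got = find_clusters(coords, box, top, contact_cutoff=1.0)
        expected = union_find_clusters(coords, box, top, cutoff=1.0)
        # same partition up to relabeling
        assert len(np.unique(got)) == len(np.unique(expected))
        for lab in np.unique(got):
            members = np.flatnonzero(got == lab)
            assert len(np.unique(expected[members])) == 1

    def test_partition_invariant_under_translation(self, cocomo2_params):
        rng = np.random.default_rng(5)
        top = toy_topology(cocomo2_params, n_chains=8, length=4)
        box = np.full(3, 8.0)
        coords = rng.random((top.n_beads, 3)) * 8.0
        a = find_clusters(coords, box, top)
        b = find_clusters(coords + np.array([3.1, -2.2, 7.9]), box, top)
        for lab in np.unique(a):
            members = np.flatnonzero(a == lab)
            assert len(np.unique(b[members])) == 1


class TestDiluteConcentration:
    def test_single_condensate_gives_zero(self):
        labels = np.zeros(20, dtype=int)
        assert dilute_concentration(labels, np.full(3, 50.0)) == 0.0

    def test_hand_arithmetic_ten_monomers(self):
        # 10 monomers in a 100 nm box: 10/(NA * 1e-18 L) = 16.6 uM
        labels = np.arange(10)
        c = dilute_concentration(labels, np.full(3, 100.0))
        assert c == pytest.approx(10 / (AVOGADRO * 1e-18) * 1e6, rel=1e-12)
        assert c == pytest.approx(16.6, abs=0.05)

    def test_halving_volume_doubles_concentration(self):
        labels = np.arange(7)
        c1 = dilute_concentration(labels, np.array([40.0, 40.0, 40.0]))
        c2 = dilute_concentration(labels, np.array([40.0, 40.0, 20.0]))
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_small_oligomers_count_as_dilute(self):
        # 8 chains in one big cluster, one dimer, one monomer
        labels = np.array([0] * 8 + [1, 1, 2])
        c = dilute_concentration(labels, np.full(3, 50.0), min_cluster_size=5)
        expected = 3 / (AVOGADRO * 50.0 ** 3 * 1e-24) * 1e6
        assert c == pytest.approx(expected, rel=1e-12)


class TestCsatEstimate:
    BOX = np.full(3, 50.0)

    def test_constant_series_exact(self, cocomo2_params):
        rep = report_from_counts([4] * 10, self.BOX, cocomo2_params)
        est = estimate_csat(rep, self.BOX, window_fraction=0.5)
        assert est.coexistence
        assert est.value == pytest.approx(
            dilute_concentration(np.arange(4), self.BOX), rel=1e-12)

    def test_alternating_series_gives_mean(self, cocomo2_params):
        rep = report_from_counts([2, 4] * 10, self.BOX, cocomo2_params)
        est = estimate_csat(rep, self.BOX, window_fraction=1.0)
        c2 = dilute_concentration(np.arange(2), self.BOX)
        c4 = dilute_concentration(np.arange(4), self.BOX)
        assert est.value == pytest.approx(0.5 * (c2 + c4), rel=1e-12)

    def test_fully_dispersed_flagged(self, cocomo2_params):
        rep = report_from_counts([4] * 10, self.BOX, cocomo2_params, largest=2)
        est = estimate_csat(rep, self.BOX)
        assert not est.coexistence and est.flag == "no coexistence"
        assert math.isnan(est.value)

    def test_fully_condensed_flagged(self, cocomo2_params):
        rep = report_from_counts([0] * 10, self.BOX, cocomo2_params)
        est = estimate_csat(rep, self.BOX)
        assert not est.coexistence and est.flag == "fully condensed"

    def test_window_exceeding_trajectory_raises(self, cocomo2_params):
        rep = report_from_counts([2] * 4, self.BOX, cocomo2_params)
        with pytest.raises(ValueError):
            estimate_csat(rep, self.BOX, window_fraction=1.5)


class TestRadiusOfGyration:
    def test_single_bead_zero(self):
        assert radius_of_gyration(np.zeros((1, 3)), np.array([10.0])) == 0.0

    def test_two_equal_masses_half_distance(self):
        coords = np.array([[0.0, 0, 0], [1.2, 0, 0]])
        rg = radius_of_gyration(coords, np.array([3.0, 3.0]))
        assert rg == pytest.approx(0.6, rel=1e-12)

    def test_matches_bruteforce_definition(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(50, 3))
        masses = rng.uniform(50, 200, size=50)
        assert radius_of_gyration(coords, masses) == pytest.approx(
            brute_rg(coords, masses), abs=1e-10)

    def test_unwrap_across_periodic_boundary(self):
        # straight chain crossing the boundary: wrapped coordinates must
        # give the same Rg as the unwrapped chain
        box = np.full(3, 5.0)
        unwrapped = np.column_stack([4.0 + 0.38 * np.arange(6),
                                     np.ones(6), np.ones(6)])
        wrapped = unwrapped.copy()
        wrapped[:, 0] %= 5.0
        masses = np.full(6, 100.0)
        assert radius_of_gyration(wrapped, masses, box=box) == pytest.approx(
            radius_of_gyration(unwrapped, masses), rel=1e-12)


class TestBuildStart:
    def make(self, params, mode, n_total=10, n_cond=None, seed=0):
        spec = ChainSpec(chain_id="t", sequence="GSGSGS", copies=n_total)
        top = build_topology([spec], params)
        cfg = StartConfig(mode=mode, n_chains_total=n_total,
                          n_chains_condensed=n_cond, box=20.0, seed=seed)
        return build_start([spec], cfg, top, params), top, cfg

    def test_mixed_mode_counts(self, cocomo2_params):
        state, top, cfg = self.make(cocomo2_params, "mixed", 10, 6)
        center = cfg.box / 2
        inside = 0
        for k, sl in enumerate(top.chain_slices()):
            centroid = state.coordinates[sl].mean(axis=0)
            if np.linalg.norm(centroid - center) < 6.0:
                inside += 1
        assert inside >= 6  # all condensed chains near the center

    def test_random_mode_min_separation(self, cocomo2_params):
        state, top, cfg = self.make(cocomo2_params, "random", 12)
        coords = state.coordinates
        chain = top.chain_index
        dmin = np.inf
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                if chain[i] == chain[j]:
                    continue
                d = coords[i] - coords[j]
                d -= cfg.box * np.round(d / cfg.box)
                dmin = min(dmin, float(np.linalg.norm(d)))
        assert dmin >= cfg.min_separation

    def test_seed_contract(self, cocomo2_params):
        s1, _, _ = self.make(cocomo2_params, "mixed", 8, 4, seed=1)
        s2, _, _ = self.make(cocomo2_params, "mixed", 8, 4, seed=2)
        s1b, _, _ = self.make(cocomo2_params, "mixed", 8, 4, seed=1)
        assert not np.allclose(s1.coordinates, s2.coordinates)
        assert np.array_equal(s1.coordinates, s1b.coordinates)

    def test_all_beads_placed(self, cocomo2_params):
        state, _, _ = self.make(cocomo2_params, "condensate", 10)
        assert np.all(np.isfinite(state.coordinates))


@given(n_dilute=st.integers(0, 50), edge=st.floats(10.0, 200.0))
@settings(max_examples=50, deadline=None)
def test_concentration_scaling_property(n_dilute, edge):
    """c is linear in count and inversely proportional to volume."""
    labels = np.arange(n_dilute) if n_dilute else np.zeros(6, dtype=int)
    box = np.full(3, edge)
    c = dilute_concentration(labels, box, min_cluster_size=5)
    expected_n = n_dilute if n_dilute else 0
    expected = expected_n / (AVOGADRO * edge ** 3 * 1e-24) * 1e6
    assert c == pytest.approx(expected, rel=1e-9)
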
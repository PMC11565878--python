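import math

import numpy as np
import pytest

from cocomo2 import (ChainSpec, SystemState, angle_energy, bond_energy,
                     build_topology, electrostatic_energy, enm_energy, forces,
                     short_range_energy, total_energy)
from cocomo2.energy import DegenerateAngleError
from cocomo2.forcefield import bead_type, combine_pair

from conftest import random_system
from reference import brute_energies

BOX = np.full(3, 10.0)


def two_bead_state(res_i, res_j, r, params, xi=(1.0, 1.0)):
    """Two single-residue chains at separation r (no bonded terms)."""
    import dataclasses
    specs = [ChainSpec(chain_id="a", sequence=res_i),
             ChainSpec(chain_id="b", sequence=res_j)]
    top = build_topology(specs, params)
    top.xi[:] = xi
    coords = np.array([[2.0, 2.0, 2.0], [2.0 + r, 2.0, 2.0]])
    return SystemState(coordinates=coords, box=BOX, topology=top, params=params)


def chain_state(sequence, coords, params, folded=None, ref=None):
    spec = ChainSpec(chain_id="c", sequence=sequence,
                     folded_ranges=folded or [],
                     reference_coordinates=ref)
    top = build_topology([spec], params)
    return SystemState(coordinates=np.asarray(coords, dtype=float), box=BOX,
                       topology=top, params=params)


class TestBondedTerms:
    def test_bond_at_equilibrium_is_zero(self, cocomo2_params):
        coords = [[0, 0, 0], [0.38, 0, 0]]
        st = chain_state("GS", coords, cocomo2_params)
        assert bond_energy(st) == pytest.approx(0.0, abs=1e-12)

    def test_bond_hand_arithmetic(self, cocomo2_params):
        # one bond stretched to 0.48 nm: 0.5 * 4184 * 0.1^2 = 20.92 kJ/mol
        st = chain_state("GS", [[0, 0, 0], [0.48, 0, 0]], cocomo2_params)
        assert bond_energy(st) == pytest.approx(20.92, rel=1e-9)

    def test_bond_additivity(self, cocomo2_params):
        one = chain_state("GS", [[0, 0, 0], [0.48, 0, 0]], cocomo2_params)
        two = chain_state("GSG", [[0, 0, 0], [0.48, 0, 0], [0.96, 0, 0]],
                          cocomo2_params)
        assert bond_energy(two) == pytest.approx(2 * bond_energy(one), rel=1e-12)

    def test_enm_zero_at_reference_and_hand_value(self, cocomo2_params):
        ref = np.array([[0, 0, 0], [0.38, 0, 0], [0.76, 0, 0.0]])
        spec = ChainSpec(chain_id="f", sequence="AAA", folded_ranges=[(1, 3)],
                         reference_coordinates=ref)
        top = build_topology([spec], cocomo2_params)
        st = SystemState(coordinates=ref.copy(), box=BOX, topology=top,
                         params=cocomo2_params)
        assert enm_energy(st) == pytest.approx(0.0, abs=1e-12)
        # displace the single (1,3) restraint by 0.02 nm: 0.5*500*4e-4 = 0.1
        moved = ref.copy()
        moved[2, 0] += 0.02
        st2 = SystemState(coordinates=moved, box=BOX, topology=top,
                          params=cocomo2_params)
        assert enm_energy(st2) == pytest.approx(0.1, rel=1e-9)

    def test_angle_zero_when_collinear(self, cocomo2_params):
        st = chain_state("GSG", [[0, 0, 0], [0.38, 0, 0], [0.76, 0, 0]],
                         cocomo2_params)
        assert angle_energy(st) == pytest.approx(0.0, abs=1e-12)

    def test_angle_right_angle_hand_value(self, cocomo2_params):
        st = chain_state("GSG", [[0.38, 0.38, 0], [0.38, 0, 0], [0.76, 0, 0]],
                         cocomo2_params)
        expected = 0.5 * 4.184 * (math.pi / 2) ** 2
        assert angle_energy(st) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(5.162, abs=1e-3)

    def test_angle_rotation_invariance(self, cocomo2_params):
        rng = np.random.default_rng(4)
        coords = np.array([[0.2, 0.1, 0.0], [0.5, 0.2, 0.1], [0.8, 0.0, 0.3]])
        st = chain_state("GSG", coords + 3.0, cocomo2_params)
        e0 = angle_energy(st)
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=7).as_matrix()
        st2 = chain_state("GSG", coords @ R.T + 3.0, cocomo2_params)
        assert angle_energy(st2) == pytest.approx(e0, rel=1e-10)

    def test_degenerate_triple_raises(self, cocomo2_params):
        with pytest.raises(DegenerateAngleError):
            angle_energy(chain_state(
                "GSG", [[0, 0, 0], [0, 0, 0], [0.4, 0, 0]], cocomo2_params))


class TestShortRange:
    def test_zero_at_sigma(self, cocomo2_params):
        g = bead_type("GLY", cocomo2_params)
        st = two_bead_state("G", "G", g.sigma, cocomo2_params)
        assert short_range_energy(st) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("res_i,res_j,xi", [
        ("G", "S", (1.0, 1.0)),
        ("R", "F", (1.0, 1.0)),   # cation-aromatic enhancement
        ("F", "Y", (0.5, 0.8)),   # aromatic pair with xi scaling
    ])
    def test_minimum_depth(self, cocomo2_params, res_i, res_j, xi):
        """U at r = 2^(1/5) sigma equals -xi_ij (eps_ij + eps_mod)."""
        bi = bead_type(res_i, cocomo2_params)
        bj = bead_type(res_j, cocomo2_params)
        pp = combine_pair(bi, bj, *xi, cocomo2_params)
        r = 2.0 ** 0.2 * pp.sigma_ij
        st = two_bead_state(res_i, res_j, r, cocomo2_params, xi=xi)
        expected = -pp.xi_ij * (pp.eps_ij + pp.eps_mod_ij)
        assert short_range_energy(st) == pytest.approx(expected, rel=1e-10)

    def test_zero_beyond_cutoff(self, cocomo2_params):
        st = two_bead_state("F", "F", 3.1, cocomo2_params)
        assert short_range_energy(st) == 0.0
        assert electrostatic_energy(st) == 0.0

    def test_exclusion_of_bonded_neighbors(self, cocomo2_params):
        # bonded pair at overlapping distance: nonbonded terms stay zero
        st = chain_state("RF", [[0, 0, 0], [0.1, 0, 0]], cocomo2_params)
        assert short_range_energy(st) == 0.0
        assert electrostatic_energy(st) == 0.0
        assert bond_energy(st) > 0.0


class TestElectrostatics:
    def test_neutral_pair_zero(self, cocomo2_params):
        # GLY-GLY under COCOMO2: q = 0 and A0_hydrophobic pair term is tiny
        # but nonzero; use polar GLN with A0_polar = 0 for an exact zero
        st = two_bead_state("Q", "Q", 0.8, cocomo2_params)
        assert electrostatic_energy(st) == pytest.approx(0.0, abs=1e-15)

    def test_opposite_charges_attract(self, cocomo2_params):
        st = two_bead_state("K", "E", 0.8, cocomo2_params)
        e = electrostatic_energy(st)
        # A_ij = -0.75^2 = -0.5625
        expected = cocomo2_params.elec_prefactor * (-0.5625) * \
            math.exp(-0.8 / 1.0) / 0.8
        assert e == pytest.approx(expected, rel=1e-10)
        assert e < 0

    def test_like_charges_repel(self, cocomo2_params):
        st = two_bead_state("K", "R", 0.8, cocomo2_params)
        assert electrostatic_energy(st) > 0

    def test_screened_decay_is_monotone(self, cocomo2_params):
        mags = []
        for r in np.linspace(0.5, 2.9, 20):
            st = two_bead_state("K", "E", float(r), cocomo2_params)
            mags.append(abs(electrostatic_energy(st)))
        assert all(a > b for a, b in zip(mags, mags[1:]))


class TestTotalAndOracle:
    def test_single_bead_all_zero(self, cocomo2_params):
        spec = ChainSpec(chain_id="one", sequence="G")
        top = build_topology([spec], cocomo2_params)
        st = SystemState(coordinates=np.array([[5.0, 5.0, 5.0]]), box=BOX,
                         topology=top, params=cocomo2_params)
        eb = total_energy(st)
        assert eb.total == 0.0

    def test_total_is_sum_of_components(self, cocomo2_params):
        st = random_system(seed=11, params=cocomo2_params)
        eb = total_energy(st)
        s = eb.bond + eb.angle + eb.enm + eb.short_range + eb.electrostatic
        assert eb.total == pytest.approx(s, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_all_terms_match_bruteforce(self, cocomo2_params, seed):
        st = random_system(n_chains=5, chain_length=10, seed=seed,
                           params=cocomo2_params, folded=(seed % 2 == 0))
        eb = total_energy(st)
        ref = brute_energies(st.coordinates, st.box, st.topology, st.params)
        for term in ("bond", "angle", "enm"):
            assert getattr(eb, term) == pytest.approx(ref[term], rel=1e-9,
                                                      abs=1e-12)
        for term in ("short_range", "electrostatic"):
            assert getattr(eb, term) == pytest.approx(ref[term], rel=1e-6,
                                                      abs=1e-10)

    def test_minimum_image_periodicity(self, cocomo2_params):
        base = two_bead_state("G", "S", 1.0, cocomo2_params)
        e0 = total_energy(base).total
        shifted = base.coordinates.copy()
        shifted[1] += BOX  # full box translation of one bead
        st2 = SystemState(coordinates=shifted, box=BOX,
                          topology=base.topology, params=cocomo2_params)
        assert total_energy(st2).total == pytest.approx(e0, rel=1e-12)

    def test_translation_invariance(self, cocomo2_params):
        st = random_system(seed=3, params=cocomo2_params)
        e0 = total_energy(st).total
        st2 = SystemState(coordinates=st.coordinates + 2.345, box=st.box,
                          topology=st.topology, params=st.params)
        assert total_energy(st2).total == pytest.approx(e0, rel=1e-9)

    def test_xi_zero_silences_short_range_not_bonded(self, cocomo2_params,
                                                     folded_bundle):
        spec, _ = folded_bundle
        top = build_topology([spec], cocomo2_params)
        rng = np.random.default_rng(0)
        coords = spec.reference_coordinates + rng.normal(scale=0.02,
                                                         size=(49, 3)) + 4.0
        st = SystemState(coordinates=coords, box=BOX, topology=top,
                         params=cocomo2_params)
        eb = total_energy(st)
        zero = top.with_lambda(None)  # all xi -> 1 first, then kill them
        zero.xi = np.zeros(49)
        st2 = SystemState(coordinates=coords, box=BOX, topology=zero,
                          params=cocomo2_params)
        eb2 = total_energy(st2)
        assert eb2.short_range == 0.0
        assert eb2.bond == pytest.approx(eb.bond, rel=1e-12)
        assert eb2.enm == pytest.approx(eb.enm, rel=1e-12)
        assert eb2.electrostatic == pytest.approx(eb.electrostatic, rel=1e-12)


class TestForces:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_forces_match_finite_differences(self, cocomo2_params, seed):
        st = random_system(n_chains=3, chain_length=8, seed=seed,
                           params=cocomo2_params)
        f = forces(st)
        rng = np.random.default_rng(seed)
        h = 1e-6
        for _ in range(6):
            i = int(rng.integers(st.topology.n_beads))
            k = int(rng.integers(3))
            xp = st.coordinates.copy()
            xp[i, k] += h
            xm = st.coordinates.copy()
            xm[i, k] -= h
            ep = total_energy(SystemState(xp, st.box, st.topology, st.params)).total
            em = total_energy(SystemState(xm, st.box, st.topology, st.params)).total
            fd = -(ep - em) / (2 * h)
            assert f[i, k] == pytest.approx(fd, rel=1e-5, abs=1e-4)
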
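"""Five-term design energy function and singles/pairs matrix assembly."""

import numpy as np
import pytest

from confdesign.energy import (COULOMB_CONSTANT, EnergyMatrices, assign_ss_class,
                               build_energy_matrices, coulomb_energy, hbond_energy,
                               lj_energy, pair_term_energy, solvation_kernel,
                               solvation_pair, solvation_penalty, ss_propensity)
from confdesign.structure import RigidTransform
from confdesign.synthetic import make_toy_structure, _rotation_about_axis


class TestLennardJones:
    def test_minimum_at_combined_radius(self, ff):
        r0c, epsc = ff.lj_params("C")
        r0o, epso = ff.lj_params("O")
        r0 = 0.5 * (r0c + r0o)
        eps = np.sqrt(epsc * epso)
        assert lj_energy(ff, "C", "O", r0) == pytest.approx(-eps, rel=1e-12)

    def test_vanishes_from_below_at_long_range(self, ff):
        e = lj_energy(ff, "C", "C", 50.0)
        assert -1e-6 < e < 0.0

    def test_zero_crossing_at_analytic_root(self, ff):
        r0, _ = ff.lj_params("N")
        assert lj_energy(ff, "N", "N", r0 * 2.0 ** (-1.0 / 6.0)) == \
            pytest.approx(0.0, abs=1e-10)

    def test_clash_capped(self, ff):
        assert lj_energy(ff, "C", "C", 1e-5) == ff.clash_cap


class TestHydrogenBond:
    def test_well_depth_at_equilibrium(self, ff):
        assert hbond_energy(ff, "N", "O", "O", 2.8) == pytest.approx(-8.0, rel=1e-12)

    def test_angular_cutoff_below_90(self, ff):
        assert hbond_energy(ff, "N", "O", "O", 2.8, theta_dha_deg=80.0) == 0.0

    def test_12_10_form_hand_evaluated(self, ff):
        q = 2.8 / 3.2
        expected = 8.0 * (5.0 * q ** 12 - 6.0 * q ** 10)
        assert hbond_energy(ff, "OG", "O", "O", 3.2) == pytest.approx(expected, rel=1e-12)

    def test_non_donor_acceptor_pair_is_zero(self, ff):
        assert hbond_energy(ff, "CB", "CG", "C", 2.8) == 0.0


class TestCoulomb:
    def test_zero_charge_gives_zero(self, ff):
        assert coulomb_energy(ff, 0.0, 0.5, 3.0) == 0.0

    def test_hand_evaluated_value(self, ff):
        expected = COULOMB_CONSTANT * 0.25 / (10.0 * 2.8 ** 2)
        assert coulomb_energy(ff, 0.5, 0.5, 2.8) == pytest.approx(expected, rel=1e-12)

    def test_opposite_charges_attract_everywhere(self, ff):
        for r in (0.5, 1.0, 2.0, 5.0, 7.9):
            assert coulomb_energy(ff, 0.4, -0.3, r) < 0.0


class TestSolvation:
    def test_isolated_atom_zero(self, ff):
        assert solvation_penalty(ff, "O", []) == 0.0

    def test_single_neighbor_hand_evaluated(self, ff):
        r = 2.0
        vref_c, _ = ff.solvation_params("C")
        _, coeff_o = ff.solvation_params("O")
        expected = coeff_o * vref_c * np.exp(-(r / ff.solv_length) ** 2)
        assert solvation_penalty(ff, "O", [("C", r)]) == pytest.approx(expected, rel=1e-12)

    def test_monotone_as_neighbor_approaches(self, ff):
        vals = [solvation_penalty(ff, "N", [("O", r)]) for r in (5.0, 4.0, 3.0, 2.0, 1.0)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_pair_share_symmetric(self, ff):
        assert solvation_pair(ff, "N", "S", 3.1) == pytest.approx(
            solvation_pair(ff, "S", "N", 3.1), rel=1e-12)


class TestSsPropensity:
    def test_table_difference_reproduced(self, ff):
        diff = ss_propensity(ff, "GLY", "helix") - ss_propensity(ff, "ALA", "helix")
        assert diff == pytest.approx(ff.ss_table["helix"]["GLY"]
                                     - ff.ss_table["helix"]["ALA"], rel=1e-12)

    def test_unknown_type_warns_and_returns_zero(self, ff):
        with pytest.warns(UserWarning):
            assert ss_propensity(ff, "XXX", "helix") == 0.0

    def test_additivity_over_sequence(self, ff):
        seq = ["ALA", "GLY", "VAL", "LEU"]
        classes = ["helix", "helix", "strand", "other"]
        total = sum(ss_propensity(ff, a, c) for a, c in zip(seq, classes))
        direct = sum(ff.ss_table[c].get(a, 0.0) for a, c in zip(seq, classes))
        assert total == pytest.approx(direct, rel=1e-12)

    def test_phi_psi_classes(self):
        assert assign_ss_class(-60.0, -45.0) == "helix"
        assert assign_ss_class(-120.0, 130.0) == "strand"
        assert assign_ss_class(60.0, 40.0) == "other"
        assert assign_ss_class(None, None) == "other"


class TestEnergyMatrices:
    @pytest.fixture()
    def toy_matrices(self, ff):
        s = make_toy_structure(8)
        positions = [("A", 3), ("A", 6)]
        cands = [[("SER", (-65.0,)), ("SER", (180.0,))],
                 [("ALA", ()), ("SER", (62.0,))]]
        return s, positions, cands, build_energy_matrices(s, positions, cands, ff)

    def test_single_choice_total_equals_single(self, ff):
        s = make_toy_structure(8)
        m = build_energy_matrices(s, [("A", 4)], [[("SER", (-65.0,))]], ff)
        assert m.assignment_energy((0,)) == pytest.approx(float(m.singles[0][0]), abs=1e-12)

    def test_far_apart_positions_have_no_pairs(self, ff):
        s = make_toy_structure(12)
        m = build_energy_matrices(s, [("A", 2), ("A", 11)],
                                  [[("SER", (-65.0,))], [("SER", (-65.0,))]], ff)
        assert m.pairs == {}

    def test_entries_match_atom_pair_oracle(self, ff, toy_matrices):
        """Brute-force recomputation of every entry from coordinates."""
        from confdesign.energy import _backbone_dihedrals, _SIDECHAIN_SKIP
        from confdesign.rotamers import build_sidechain

        s, positions, cands, m = toy_matrices
        built = []
        for (cid, num), cand in zip(positions, cands):
            res = s.get_residue(cid, num)
            bb = {n: res.atom(n).coords for n in ("N", "CA", "C")}
            built.append([build_sidechain(aa, chi, bb) for aa, chi in cand])
        # independent singles for position 0 choice 1
        chain = s.chains[0]
        designed = {(cid, n) for cid, n in positions}
        e = ss_propensity(ff, cands[0][1][0],
                          assign_ss_class(*_backbone_dihedrals(chain.residues, 2)))
        for an, ae, axyz in built[0][1]:
            for res in chain.residues:
                key = ("A", res.number)
                if key == positions[0]:
                    continue
                for t in res.atoms:
                    if key in designed and t.name not in _SIDECHAIN_SKIP:
                        continue
                    e += pair_term_energy(ff, an, ae, axyz, t.name, t.element, t.coords)
        assert float(m.singles[0][1]) == pytest.approx(min(e, ff.clash_cap), abs=1e-9)
        # independent pair for (0,1) choices (1, 1)
        ep = 0.0
        for an, ae, axyz in built[0][1]:
            for bn, be, bxyz in built[1][1]:
                ep += pair_term_energy(ff, an, ae, axyz, bn, be, bxyz)
        assert m.pair(0, 1, 1, 1) == pytest.approx(min(ep, ff.clash_cap), abs=1e-9)

    def test_assignment_decomposability(self, toy_matrices):
        _, _, _, m = toy_matrices
        for assign in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            direct = sum(float(m.singles[i][r]) for i, r in enumerate(assign))
            direct += m.pair(0, assign[0], 1, assign[1])
            assert m.assignment_energy(assign) == pytest.approx(direct, abs=1e-9)

    def test_symmetric_pair_access(self, toy_matrices):
        _, _, _, m = toy_matrices
        assert m.pair(0, 1, 1, 0) == m.pair(1, 0, 0, 1)

    def test_invariant_under_global_rigid_motion(self, ff):
        s = make_toy_structure(8)
        positions = [("A", 3), ("A", 6)]
        cands = [[("SER", (-65.0,))], [("VAL", (180.0,))]]
        m0 = build_energy_matrices(s, positions, cands, ff)
        tr = RigidTransform(_rotation_about_axis((0.3, 1.0, 0.5), 61.0),
                            np.array([5.0, -3.0, 8.0]))
        m1 = build_energy_matrices(tr.apply_to_structure(s), positions, cands, ff)
        for a, b in zip(m0.singles, m1.singles):
            np.testing.assert_allclose(a, b, atol=1e-8)

    def test_csv_round_trip(self, tmp_path, toy_matrices):
        _, _, _, m = toy_matrices
        m.to_csv(tmp_path)
        m2 = EnergyMatrices.from_csv(tmp_path)
        for a, b in zip(m.singles, m2.singles):
            np.testing.assert_allclose(a, b, rtol=1e-12)
        for k in m.pairs:
            np.testing.assert_allclose(m.pairs[k], m2.pairs[k], rtol=1e-12)
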
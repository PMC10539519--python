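"""Sequence enumeration, Boltzmann state energies, ΔE ranking, CLEARSS."""

import math
from itertools import combinations, product

import numpy as np
import pytest

from confdesign.multistate import (R_GAS, LibraryDesign, SequenceDesignRecord,
                                   boltzmann_average, clearss_design,
                                   count_sequences, enumerate_sequences,
                                   rank_by_delta_e, state_energy)
from confdesign.rotamers import DESIGN_ALPHABET


class TestEnumeration:
    def test_design_space_of_four_positions(self):
        assert count_sequences(4, DESIGN_ALPHABET) == 130_321
        _, n = enumerate_sequences(4, DESIGN_ALPHABET)
        assert n == 19 ** 4

    def test_single_position_two_letters(self):
        it, n = enumerate_sequences(1, ["B", "A"])
        assert list(it) == [("A",), ("B",)]
        assert n == 2

    def test_count_equals_materialized_length(self):
        it, n = enumerate_sequences(3, "ACD")
        assert len(list(it)) == n == 27


class TestBoltzmannAverage:
    def test_equal_energies_give_that_energy(self):
        assert boltzmann_average([2.5, 2.5, 2.5], 300.0) == pytest.approx(2.5, rel=1e-12)

    def test_two_member_hand_evaluation(self):
        rt = R_GAS * 300.0
        w0, w1 = 1.0, math.exp(-1.0 / rt)
        expected = (0.0 * w0 + 1.0 * w1) / (w0 + w1)
        assert boltzmann_average([0.0, 1.0], 300.0) == pytest.approx(expected, rel=1e-12)

    def test_low_temperature_limit_is_min(self):
        e = [3.0, -1.0, 5.0]
        assert boltzmann_average(e, 1e-9) == pytest.approx(-1.0, abs=1e-9)

    def test_bounded_by_min_and_mean(self, rng):
        for _ in range(20):
            e = rng.normal(0, 5, size=8)
            avg = boltzmann_average(e, 300.0)
            assert e.min() - 1e-12 <= avg <= e.mean() + 1e-12

    def test_overflow_safe_for_large_magnitudes(self):
        assert np.isfinite(boltzmann_average([-4000.0, -3990.0], 300.0))


class TestStateEnergy:
    def test_boltzmann_over_member_optima(self):
        class _Ens:
            members = ["m1", "m2"]

        calls = []

        def builder(member):
            calls.append(member)
            from confdesign.synthetic import make_toy_design_problem
            return make_toy_design_problem(2, 3, seed=len(calls), n_aa=1).matrices

        e = state_energy(("A", "A"), _Ens(), builder, temperature=300.0)
        from confdesign.solvers import faster_optimize
        from confdesign.synthetic import make_toy_design_problem
        expected = boltzmann_average(
            [faster_optimize(make_toy_design_problem(2, 3, seed=k, n_aa=1).matrices,
                             seq=("A", "A")).total_energy for k in (1, 2)], 300.0)
        assert e == pytest.approx(expected, rel=1e-12)


class TestRanking:
    def test_delta_e_identity(self):
        r = SequenceDesignRecord(("V",), -358.0, -372.2)
        assert r.delta_e == pytest.approx(14.2, abs=1e-9)

    def test_percentile_filter_matches_direct_computation(self):
        recs = [SequenceDesignRecord((a,), ec, eo) for a, ec, eo in
                [("A", -10.0, -8.0), ("C", -6.0, -9.0), ("D", -8.0, -2.0), ("E", -12.0, -7.0)]]
        out = rank_by_delta_e(recs, percentile=75.0, objective="closed")
        thr_c = np.percentile([r.e_closed for r in recs], 75)
        thr_o = np.percentile([r.e_open for r in recs], 75)
        expected = sorted([r for r in recs if r.e_closed <= thr_c and r.e_open <= thr_o],
                          key=lambda r: r.delta_e)
        assert [r.sequence for r in out] == [r.sequence for r in expected]

    def test_single_record_survives(self):
        recs = [SequenceDesignRecord(("A",), -5.0, -1.0)]
        assert rank_by_delta_e(recs) == recs

    def test_open_objective_sorts_descending(self):
        recs = [SequenceDesignRecord((a,), ec, eo) for a, ec, eo in
                [("A", -1.0, -5.0), ("C", -5.0, -1.0)]]
        out = rank_by_delta_e(recs, percentile=100.0, objective="open")
        assert out[0].delta_e >= out[-1].delta_e

    def test_swapping_states_negates_delta_e(self):
        r = SequenceDesignRecord(("A", "C"), -350.2, -273.4)
        swapped = SequenceDesignRecord(("A", "C"), r.e_open, r.e_closed)
        assert swapped.delta_e == pytest.approx(-r.delta_e, abs=1e-12)


def _independent_clearss(records, target, tol, t_sel, objective="closed"):
    """Exhaustive configuration search written independently of the solver."""
    sign = 1.0 if objective == "closed" else -1.0
    n = len(records[0].sequence)
    scores = [sign * r.delta_e for r in records]
    shift = min(scores)
    w = [{} for _ in range(n)]
    for r, sc in zip(records, scores):
        for i, aa in enumerate(r.sequence):
            w[i][aa] = w[i].get(aa, 0.0) + math.exp(-(sc - shift) / t_sel)
    ordered = [sorted(d, key=lambda a: (-d[a], a)) for d in w]
    best = None
    for config in product(*(range(1, len(o) + 1) for o in ordered)):
        size = math.prod(config)
        if not max(target - tol, 1) <= size <= target + tol:
            continue
        sets = tuple(tuple(sorted(ordered[i][:config[i]])) for i in range(n))
        score = sum(w[i][a] for i in range(n) for a in sets[i])
        key = (-score, size, sets)
        if best is None or key < best:
            best = key
    return best


class TestClearss:
    def _records(self):
        rng = np.random.default_rng(12)
        recs = []
        for s1 in "ACDEF":
            for s2 in "ACD":
                recs.append(SequenceDesignRecord((s1, s2), rng.normal(-10, 3),
                                                 rng.normal(-8, 3)))
        return recs

    def test_single_position_top_k(self):
        recs = [SequenceDesignRecord((a,), e, 0.0)
                for a, e in [("A", -3.0), ("C", -2.0), ("D", -1.0), ("E", 0.0)]]
        lib = clearss_design(recs, target=3, tol=0)
        assert lib.position_sets == [("A", "C", "D")]

    def test_matches_independent_configuration_search(self):
        recs = self._records()
        lib = clearss_design(recs, target=6, tol=2)
        best = _independent_clearss(recs, 6, 2, 1.0)
        sets = tuple(tuple(s) for s in lib.position_sets)
        assert (-lib.score, lib.size, sets) == pytest.approx(best[0]) or sets == best[2]
        assert lib.score == pytest.approx(-best[0], rel=1e-12)

    def test_size_within_tolerance_window(self):
        recs = self._records()
        for target, tol in [(6, 2), (8, 3), (4, 1)]:
            lib = clearss_design(recs, target=target, tol=tol)
            assert max(target - tol, 1) <= lib.size <= target + tol

    def test_score_monotone_in_tolerance(self):
        recs = self._records()
        scores = [clearss_design(recs, target=6, tol=t).score for t in (0, 1, 2, 3)]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_infeasible_target_raises(self):
        recs = [SequenceDesignRecord((a,), -1.0, 0.0) for a in "AC"]
        with pytest.raises(ValueError, match="configuration"):
            clearss_design(recs, target=50, tol=0)

    def test_member_sequences_product(self):
        lib = LibraryDesign([("A", "C"), ("D", "E", "F")], 1.0, target=6, tolerance=0)
        assert lib.size == 6
        assert len(lib.member_sequences()) == 6
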
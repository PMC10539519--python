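"""Rotamer-assignment solvers over singles/pairs energy matrices.

Three routes with one contract (minimize Σ singles + Σ pairs, one choice per
position): an exhaustive global-minimum oracle for small problems, Goldstein
dead-end elimination as a provably GMEC-preserving pre-filter, and the FASTER
heuristic (iterative batch relaxation followed by single-perturbation/
relaxation sweeps).  All tie-breaking is lexicographic (position order, then
choice order), so every solver is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .energy import EnergyMatrices

__all__ = ["RotamerAssignment", "brute_force_gmec", "dee_prune", "faster_optimize"]

BRUTE_FORCE_BOUND = 10 ** 6


@dataclass
class RotamerAssignment:
    """One chosen (aa, rotamer) per position plus the total energy."""

    indices: tuple[int, ...]
    choices: tuple
    total_energy: float
    converged: bool = True


def _as_assignment(m: EnergyMatrices, idx, converged=True) -> RotamerAssignment:
    idx = tuple(int(i) for i in idx)
    return RotamerAssignment(idx, tuple(m.choices[i][r] for i, r in enumerate(idx)),
                             m.assignment_energy(idx), converged)


def brute_force_gmec(m: EnergyMatrices) -> RotamerAssignment:
    """Exact global minimum by exhaustive enumeration (small problems only).

    Refuses search spaces above ``BRUTE_FORCE_BOUND``; lexicographically
    first assignment wins ties.
    """
    space = 1
    for i in range(m.n_positions):
        space *= m.n_choices(i)
        if space > BRUTE_FORCE_BOUND:
            raise ValueError(f"search space exceeds bound {BRUTE_FORCE_BOUND}")
    best_idx, best_e = None, np.inf
    for idx in product(*(range(m.n_choices(i)) for i in range(m.n_positions))):
        e = m.assignment_energy(idx)
        if e < best_e:  # strict: keeps the lexicographically first optimum
            best_idx, best_e = idx, e
    return _as_assignment(m, best_idx)


def dee_prune(m: EnergyMatrices) -> EnergyMatrices:
    """Goldstein dead-end elimination, iterated to a fixpoint.

    Eliminates choice i_r whenever some competitor i_t satisfies
    E(i_r) − E(i_t) + Σ_{j≠i} min_s [E(i_r, j_s) − E(i_t, j_s)] > 0,
    which proves i_r cannot be part of the GMEC.
    """
    alive = [list(range(m.n_choices(i))) for i in range(m.n_positions)]
    n = m.n_positions
    changed = True
    while changed:
        changed = False
        for i in range(n):
            if len(alive[i]) == 1:
                continue
            doomed = []
            for r in alive[i]:
                for t in alive[i]:
                    if t == r:
                        continue
                    gap = float(m.singles[i][r] - m.singles[i][t])
                    for j in range(n):
                        if j == i:
                            continue
                        gap += min(m.pair(i, r, j, s) - m.pair(i, t, j, s)
                                   for s in alive[j])
                    if gap > 0.0:
                        doomed.append(r)
                        break
            if doomed:
                alive[i] = [r for r in alive[i] if r not in doomed]
                changed = True
            if not alive[i]:
                raise ValueError(f"position {m.positions[i]} pruned to zero choices")
    new_choices = [[m.choices[i][r] for r in alive[i]] for i in range(n)]
    new_singles = [m.singles[i][alive[i]] for i in range(n)]
    new_pairs = {(i, j): mat[np.ix_(alive[i], alive[j])]
                 for (i, j), mat in m.pairs.items()}
    return EnergyMatrices(list(m.positions), new_choices, new_singles, new_pairs)


def _conditional_best(m: EnergyMatrices, cur: list[int], i: int) -> int:
    """Best choice at i given the current choices elsewhere (lexicographic ties)."""
    best_r, best_e = 0, np.inf
    for r in range(m.n_choices(i)):
        e = float(m.singles[i][r])
        for j in range(m.n_positions):
            if j != i:
                e += m.pair(i, r, j, cur[j])
        if e < best_e - 1e-12:
            best_r, best_e = r, e
    return best_r


def _ibr(m: EnergyMatrices, cur: list[int], max_cycles: int = 100) -> tuple[list[int], bool]:
    """Iterative batch relaxation: each position takes its conditional best."""
    for _ in range(max_cycles):
        changed = False
        for i in range(m.n_positions):
            r = _conditional_best(m, cur, i)
            if r != cur[i]:
                cur[i] = r
                changed = True
        if not changed:
            return cur, True
    return cur, False


def faster_optimize(m: EnergyMatrices, seq=None, seed: int = 0,
                    max_cycles: int = 100) -> RotamerAssignment:
    """FASTER heuristic: batch relaxation plus single-perturbation sweeps.

    Starts from the per-position singles minima, runs iterative batch
    relaxation (iBR) to convergence, then single-perturbation/relaxation
    (sPR): each candidate rotamer is clamped in turn, the rest relaxed, and
    the move accepted only on strict energy improvement.  ``seq`` optionally
    constrains the amino acid at each position.  Deterministic for a fixed
    seed and sweep order; the result never beats the exact GMEC and never
    loses to the initialization.
    """
    if seq is not None:
        m = m.restrict([{aa} for aa in seq])
    del seed  # sweep order is fixed; the seed is accepted for interface stability

    cur = [int(np.argmin(m.singles[i])) for i in range(m.n_positions)]
    cur, converged = _ibr(m, cur, max_cycles)
    best = list(cur)
    best_e = m.assignment_energy(best)

    for _ in range(max_cycles):
        improved = False
        for i in range(m.n_positions):
            for r in range(m.n_choices(i)):
                if r == best[i]:
                    continue
                trial = list(best)
                trial[i] = r
                # relax all other positions with i clamped
                for _ in range(max_cycles):
                    changed = False
                    for j in range(m.n_positions):
                        if j == i:
                            continue
                        rj = _conditional_best(m, trial, j)
                        if rj != trial[j]:
                            trial[j] = rj
                            changed = True
                    if not changed:
                        break
                e = m.assignment_energy(trial)
                if e < best_e - 1e-12:
                    best, best_e = trial, e
                    improved = True
        if not improved:
            break
    else:
        converged = False
    return _as_assignment(m, best, converged)
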
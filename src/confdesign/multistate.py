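"""Multistate design: Boltzmann-weighted state energies, ΔE ranking, CLEARSS.

For each candidate sequence the side-chain assignment is optimized on every
member of the open-state and closed-state backbone ensembles; the per-state
energy is the Boltzmann-weighted average of member energies at 300 K, and
sequences are ranked by ΔE = E_closed − E_open after discarding sequences
whose E_closed and/or E_open fall outside (above) the 75th percentile.
CLEARSS turns the ranked records into a combinatorial library of a target
size (default 20 ± 4 sequences) by scoring per-position amino-acid sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .solvers import faster_optimize

R_GAS = 1.9872e-3  # kcal/(mol·K)

__all__ = [
    "SequenceDesignRecord",
    "LibraryDesign",
    "enumerate_sequences",
    "count_sequences",
    "boltzmann_average",
    "state_energy",
    "rank_by_delta_e",
    "records_to_frame",
    "clearss_design",
]


@dataclass(frozen=True)
class SequenceDesignRecord:
    """One designed sequence with its two state energies (kcal/mol)."""

    sequence: tuple[str, ...]
    e_closed: float
    e_open: float

    @property
    def delta_e(self) -> float:
        return self.e_closed - self.e_open


@dataclass
class LibraryDesign:
    """Per-position amino-acid sets defining a combinatorial library."""

    position_sets: list[tuple[str, ...]]
    score: float
    target: int = 20
    tolerance: int = 4

    def __post_init__(self) -> None:
        if any(len(s) == 0 for s in self.position_sets):
            raise ValueError("every position set must be non-empty")
        lo, hi = self.target - self.tolerance, self.target + self.tolerance
        if not lo <= self.size <= hi:
            raise ValueError(f"library size {self.size} outside [{lo}, {hi}]")

    @property
    def size(self) -> int:
        return math.prod(len(s) for s in self.position_sets)

    def member_sequences(self) -> list[tuple[str, ...]]:
        return list(product(*self.position_sets))


def enumerate_sequences(n_positions: int, alphabet):
    """Lexicographic iterator over |alphabet|^n sequences (count returned too)."""
    alphabet = sorted(alphabet)
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    return product(alphabet, repeat=n_positions), len(alphabet) ** n_positions


def count_sequences(n_positions: int, alphabet) -> int:
    return len(set(alphabet)) ** n_positions


def boltzmann_average(energies, temperature: float = 300.0) -> float:
    """Boltzmann-weighted mean Ē = Σ E_b·w_b, w_b ∝ exp(−E_b/RT).

    Log-sum-exp stabilized, so very favorable members do not overflow.
    Bounded by min(E) ≤ Ē ≤ mean(E).
    """
    e = np.asarray(list(energies), dtype=float)
    if e.size == 0:
        raise ValueError("no member energies")
    if temperature <= 0:
        return float(e.min())
    x = -e / (R_GAS * temperature)
    x -= x.max()
    w = np.exp(x)
    w /= w.sum()
    return float(np.dot(w, e))


def state_energy(seq, ensemble, m_builder, temperature: float = 300.0,
                 solver=faster_optimize) -> float:
    """Boltzmann-weighted ensemble energy of one sequence on one state.

    ``m_builder(member)`` must return the :class:`~confdesign.energy.EnergyMatrices`
    for the member backbone; the sequence's side chains are optimized on each
    member and the member energies are Boltzmann-averaged at ``temperature``.
    """
    member_energies = []
    for member in ensemble.members:
        m = m_builder(member)
        member_energies.append(solver(m, seq=seq).total_energy)
    return boltzmann_average(member_energies, temperature)


def rank_by_delta_e(records, percentile: float = 75.0,
                    objective: str = "closed") -> list[SequenceDesignRecord]:
    """Percentile-filter and sort design records by ΔE.

    Discards any record whose E_closed is above the ``percentile`` of all
    E_closed values or whose E_open is above the percentile of all E_open
    values (unfavorably high energy in either state), then sorts survivors
    by ΔE: ascending for the closed objective (most closed-stabilizing
    first), descending for the open objective.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to rank")
    if objective not in ("closed", "open"):
        raise ValueError(f"unknown objective {objective!r}")
    thr_closed = float(np.percentile([r.e_closed for r in records], percentile))
    thr_open = float(np.percentile([r.e_open for r in records], percentile))
    survivors = [r for r in records
                 if r.e_closed <= thr_closed and r.e_open <= thr_open]
    if not survivors:
        raise ValueError("percentile filter removed every record")
    sign = 1.0 if objective == "closed" else -1.0
    return sorted(survivors, key=lambda r: (sign * r.delta_e, r.sequence))


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame({
        "sequence": ["".join(r.sequence) for r in records],
        "e_closed": [r.e_closed for r in records],
        "e_open": [r.e_open for r in records],
        "delta_e": [r.delta_e for r in records],
    })


def _position_weights(records, objective: str, t_sel: float):
    """Unnormalized per-position amino-acid partition functions over ΔE."""
    sign = 1.0 if objective == "closed" else -1.0
    n = len(records[0].sequence)
    # stabilize: shift ΔE by the best (most favorable after sign) value
    scores = [sign * r.delta_e for r in records]
    shift = min(scores)
    weights: list[dict[str, float]] = [{} for _ in range(n)]
    for r, sc in zip(records, scores):
        w = math.exp(-(sc - shift) / t_sel)
        for i, aa in enumerate(r.sequence):
            weights[i][aa] = weights[i].get(aa, 0.0) + w
    return weights


def clearss_design(records, target: int = 20, tol: int = 4,
                   t_sel: float = 1.0, objective: str = "closed") -> LibraryDesign:
    """Combinatorial library design by scored size configurations (CLEARSS).

    Per-position amino-acid weights are Boltzmann sums over the records' ΔE
    values at a selection temperature ``t_sel`` (kcal/mol).  Every size
    configuration (n₁, …, n_k) whose product lies within target ± tol is
    evaluated by placing the top-nᵢ amino acids (by weight) at each position;
    the configuration score is the sum of the chosen sets' partition
    functions and the best-scoring library is returned.  Ties prefer the
    smaller library, then lexicographic sets.
    """
    records = list(records)
    if not records:
        raise ValueError("no records for library design")
    if t_sel <= 0:
        raise ValueError("t_sel must be > 0")
    weights = _position_weights(records, objective, t_sel)
    n = len(weights)
    # amino acids per position ordered by decreasing weight (ties: alphabetic)
    ordered = [sorted(w, key=lambda a: (-w[a], a)) for w in weights]
    max_n = [len(o) for o in ordered]
    lo, hi = target - tol, target + tol
    if lo <= 0:
        lo = 1

    best = None  # (score, size, sets)
    def _recurse(i: int, size: int, config: list[int]):
        nonlocal best
        if i == n:
            if lo <= size <= hi:
                sets = tuple(tuple(sorted(ordered[k][:config[k]])) for k in range(n))
                score = sum(weights[k][a] for k in range(n) for a in sets[k])
                key = (-score, size, sets)
                if best is None or key < best[0]:
                    best = (key, score, sets)
            return
        for ni in range(1, max_n[i] + 1):
            if size * ni > hi:
                break
            _recurse(i + 1, size * ni, config + [ni])

    _recurse(0, 1, [])
    if best is None:
        raise ValueError(f"no size configuration reaches a library of {target}±{tol}")
    _, score, sets = best
    return LibraryDesign(list(sets), score, target, tol)
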
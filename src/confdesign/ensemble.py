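"""PertMin-style backbone ensemble generation.

Each ensemble member is produced by perturbing every heavy-atom coordinate by
a fixed magnitude with random sign along each Cartesian axis (Rademacher
signs, default ±0.001 Å) and then relaxing the perturbed structure with a
bounded, deterministic minimizer, so that members populate nearby local
minima of the potential.  The bundled potential is a simplified
elastic-network model (harmonic restraints on reference interatomic
distances); any object exposing ``energy_gradient(flat_coords)`` can be
substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial import cKDTree

from .structure import Structure, rmsd_between

__all__ = [
    "EnsembleSpec",
    "ConformationalEnsemble",
    "HarmonicWellPotential",
    "ElasticNetworkPotential",
    "perturb_structure",
    "minimize",
    "generate_ensemble",
    "ensemble_diversity",
]


@dataclass
class EnsembleSpec:
    n_members: int = 50
    perturbation: float = 0.001     # Å, per axis
    minimizer_iterations: int = 100
    seed: int = 0
    potential: str = "elastic_lj"

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("n_members must be ≥ 2")
        if self.perturbation <= 0:
            raise ValueError("perturbation must be > 0")


@dataclass
class ConformationalEnsemble:
    members: list[Structure]
    spec: EnsembleSpec
    seed_structure: Structure
    provenance: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Potentials


class HarmonicWellPotential:
    """Isotropic harmonic well per atom around fixed centers (test potential)."""

    def __init__(self, centers: np.ndarray, k: float = 1.0):
        self.centers = np.asarray(centers, dtype=float).reshape(-1, 3)
        self.k = float(k)

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        d = x.reshape(-1, 3) - self.centers
        return 0.5 * self.k * float((d ** 2).sum()), (self.k * d).ravel()


class ElasticNetworkPotential:
    """Harmonic distance restraints plus an optional Lennard-Jones tail.

    Short-range pairs (within ``cutoff``) carry harmonic restraints
    E = Σ k/2 (|r_ij| − d⁰_ij)² with reference distances d⁰ taken from the
    input geometry (a stand-in for bond-length/angle terms); with
    ``nonbonded=True`` pairs in (cutoff, nb_cutoff] additionally feel the
    12-6 van der Waals term of the design energy function, so the relaxed
    minimum lies genuinely near — but not exactly at — the seed geometry.
    """

    def __init__(self, reference: Structure, cutoff: float = 5.0, k: float = 10.0,
                 nonbonded: bool = True, nb_cutoff: float = 8.0):
        xyz = reference.coords_array()
        tree = cKDTree(xyz)
        pairs = sorted(tree.query_pairs(cutoff))
        if not pairs:
            raise ValueError("no atom pairs within cutoff; cannot build network")
        self.i = np.array([p[0] for p in pairs])
        self.j = np.array([p[1] for p in pairs])
        self.d0 = np.linalg.norm(xyz[self.i] - xyz[self.j], axis=1)
        self.k = float(k)
        self.n_atoms = xyz.shape[0]

        self.nb_i = np.array([], dtype=int)
        self.nb_j = np.array([], dtype=int)
        self.nb_r0 = np.array([])
        self.nb_eps = np.array([])
        if nonbonded:
            from .energy import ForceFieldTables

            ff = ForceFieldTables()
            elements = [a.element for a in reference.iter_atoms()]
            far = sorted(tree.query_pairs(nb_cutoff) - set(pairs))
            if far:
                self.nb_i = np.array([p[0] for p in far])
                self.nb_j = np.array([p[1] for p in far])
                params = [ (ff.lj_params(elements[a]), ff.lj_params(elements[b]))
                           for a, b in far ]
                self.nb_r0 = np.array([0.5 * (pa[0] + pb[0]) for pa, pb in params])
                self.nb_eps = np.array([math.sqrt(pa[1] * pb[1]) for pa, pb in params])

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        xyz = x.reshape(self.n_atoms, 3)
        grad = np.zeros_like(xyz)

        dv = xyz[self.i] - xyz[self.j]
        d = np.linalg.norm(dv, axis=1)
        delta = d - self.d0
        e = 0.5 * self.k * float((delta ** 2).sum())
        unit = dv / np.maximum(d, 1e-12)[:, None]
        f = self.k * delta[:, None] * unit
        np.add.at(grad, self.i, f)
        np.add.at(grad, self.j, -f)

        if self.nb_i.size:
            dv = xyz[self.nb_i] - xyz[self.nb_j]
            d = np.maximum(np.linalg.norm(dv, axis=1), 1e-6)
            q = (self.nb_r0 / d) ** 6
            e += float((self.nb_eps * (q * q - 2.0 * q)).sum())
            dedr = self.nb_eps * 12.0 * (q - q * q) / d
            f = dedr[:, None] * (dv / d[:, None])
            np.add.at(grad, self.nb_i, f)
            np.add.at(grad, self.nb_j, -f)
        return e, grad.ravel()


def make_potential(name: str, reference: Structure):
    if name == "elastic_lj":
        return ElasticNetworkPotential(reference, nonbonded=True)
    if name == "elastic_network":
        return ElasticNetworkPotential(reference, nonbonded=False)
    raise ValueError(f"unknown potential {name!r}")


# ---------------------------------------------------------------------------
# Operations


def perturb_structure(s: Structure, magnitude: float, rng_seed: int) -> Structure:
    """Shift every heavy-atom coordinate by ±magnitude along each axis.

    Signs are independent Rademacher draws from a seeded generator, so every
    heavy atom moves by exactly magnitude·√3 in Euclidean norm; hydrogens are
    untouched.  Deterministic for a fixed seed.
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be > 0")
    rng = np.random.default_rng(rng_seed)
    out = s.copy()
    for atom in out.iter_atoms():
        if atom.is_hydrogen:
            continue
        signs = rng.integers(0, 2, size=3) * 2 - 1
        atom.coords = atom.coords + magnitude * signs
    return out


def minimize(s: Structure, potential, max_iter: int = 100) -> tuple[Structure, float]:
    """Bounded deterministic energy minimization (truncated Newton).

    Uses a Newton conjugate-gradient descent with monotone line search,
    capped at ``max_iter`` outer iterations.  Returns the relaxed structure
    and the final RMS gradient.  Energy never increases; a structure already
    at a minimum is returned unchanged.
    """
    if isinstance(potential, str):
        potential = make_potential(potential, s)
    x0 = s.coords_array().ravel()
    e0, g0 = potential.energy_gradient(x0)
    if not np.isfinite(e0):
        raise ValueError("non-finite energy at start of minimization")
    grms0 = float(np.sqrt((g0 ** 2).mean()))
    if grms0 < 1e-12:
        return s.copy(), grms0

    res = _scipy_minimize(potential.energy_gradient, x0, jac=True, method="Newton-CG",
                          options={"maxiter": max_iter, "xtol": 1e-12})
    x, e = res.x, float(res.fun)
    if not np.isfinite(e) or e > e0 + 1e-12:
        # fallback: plain steepest descent with backtracking
        x, e = _steepest_descent(potential, x0, e0, g0, max_iter)
    _, g = potential.energy_gradient(x)
    out = s.copy()
    out.set_coords_array(x.reshape(-1, 3))
    return out, float(np.sqrt((g ** 2).mean()))


def _steepest_descent(potential, x, e, g, max_iter):
    step = 1e-3
    for _ in range(max_iter):
        for _ in range(30):
            x_new = x - step * g
            e_new, g_new = potential.energy_gradient(x_new)
            if np.isfinite(e_new) and e_new < e:
                x, e, g = x_new, e_new, g_new
                step *= 1.5
                break
            step *= 0.5
        else:
            break
    return x, e


def generate_ensemble(s: Structure, spec: EnsembleSpec) -> ConformationalEnsemble:
    """Generate an n-member perturb-and-minimize ensemble.

    Member i uses seed ``spec.seed + i`` so runs are reproducible and the
    perturbation streams are independent.
    """
    potential = make_potential(spec.potential, s)
    members, provenance = [], []
    for i in range(spec.n_members):
        seed_i = spec.seed + i
        perturbed = perturb_structure(s, spec.perturbation, seed_i)
        try:
            relaxed, grms = minimize(perturbed, potential, spec.minimizer_iterations)
        except Exception as exc:
            raise RuntimeError(f"minimization failed for ensemble member {i}: {exc}") from exc
        if relaxed.n_atoms != s.n_atoms:
            raise RuntimeError(f"member {i} lost atoms during minimization")
        members.append(relaxed)
        provenance.append({"member": i, "seed": seed_i, "final_gradient_rms": grms})
    return ConformationalEnsemble(members, spec, s, provenance)


def ensemble_diversity(e: ConformationalEnsemble):
    """Ensemble diversity statistics on backbone atoms.

    Returns ``((mean_pairwise_rmsd, sd), (mean_rmsd_to_seed, sd))`` over all
    n(n−1)/2 member pairs and all members vs the seed structure, each RMSD
    computed after superposition.
    """
    if len(e) < 2:
        raise ValueError("diversity needs ≥2 members")
    pair_vals = [rmsd_between(a, b, "::backbone", fit=True)
                 for a, b in combinations(e.members, 2)]
    seed_vals = [rmsd_between(m, e.seed_structure, "::backbone", fit=True)
                 for m in e.members]
    stat = lambda v: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
    return stat(pair_vals), stat(seed_vals)
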
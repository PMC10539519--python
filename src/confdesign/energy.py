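"""Five-term pairwise design energy function and singles/pairs matrices.

Terms: Lennard-Jones 12-6 van der Waals (per-type radii scaled by 0.9,
arithmetic-mean combination, geometric-mean well depth), a direction-dependent
hydrogen bond (hybrid 12-10 with 8.0 kcal/mol well depth at 2.8 Å
donor-acceptor distance), Coulomb electrostatics with a distance-dependent
dielectric ε(r) = 10·r, a Gaussian occlusion-based solvation penalty, and a
position-additive secondary-structure propensity.  All terms are pairwise
decomposable so design energetics can be precomputed as per-position singles
(rotamer ↔ template) and pairs (rotamer ↔ rotamer) matrices; the
template ↔ template constant is excluded.

Parameter tables ship in ``data/forcefield.yaml``; they are a self-consistent
stand-in, so absolute energies are meaningful only relative to each other.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .rotamers import CHI_DEFS, build_sidechain, dihedral
from .structure import Structure

COULOMB_CONSTANT = 332.0637  # kcal·Å/(mol·e²)
R_MIN_FLOOR = 1e-3           # Å, below this a contact is a capped clash

__all__ = [
    "ForceFieldTables",
    "EnergyMatrices",
    "lj_energy",
    "hbond_energy",
    "coulomb_energy",
    "solvation_penalty",
    "ss_propensity",
    "assign_ss_class",
    "pair_term_energy",
    "build_energy_matrices",
]


class ForceFieldTables:
    """Versioned nonbonded parameter tables loaded from YAML."""

    def __init__(self, path=None):
        if path is None:
            path = resources.files("confdesign").joinpath("data/forcefield.yaml")
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        self.version: str = cfg["version"]
        self.lj_scale: float = float(cfg["lj_scale"])
        self.clash_cap: float = float(cfg["clash_cap"])
        self.cutoff: float = float(cfg["cutoff"])
        self.hbond_d0: float = float(cfg["hbond"]["d0"])
        self.hbond_r0: float = float(cfg["hbond"]["r0"])
        self.hbond_max: float = float(cfg["hbond"]["max_distance"])
        self.dielectric_model: str = cfg["dielectric"]["model"]
        self.dielectric: float = float(cfg["dielectric"]["epsilon"])
        self.solv_length: float = float(cfg["solvation"]["length"])
        self.elements: dict[str, dict] = cfg["elements"]
        self._charge_names: dict[str, float] = cfg["charges"]["names"]
        self._charge_prefixes: dict[str, float] = cfg["charges"]["prefixes"]
        self.donor_names = set(cfg["donors"])
        self.acceptor_elements = set(cfg["acceptor_elements"])
        self.acceptor_names = set(cfg["acceptor_names"])
        self.ss_table: dict[str, dict[str, float]] = cfg["ss_propensity"]

    def _elem(self, element: str) -> dict:
        e = self.elements.get(element.upper())
        if e is None:
            raise KeyError(f"no force-field parameters for element {element!r}")
        return e

    def lj_params(self, element: str) -> tuple[float, float]:
        """(scaled r0, epsilon) for an element type."""
        e = self._elem(element)
        return e["r0"] * self.lj_scale, e["eps"]

    def charge(self, atom_name: str) -> float:
        name = atom_name.upper()
        if name in self._charge_names:
            return self._charge_names[name]
        return self._charge_prefixes.get(name[:1], 0.0)

    def solvation_params(self, element: str) -> tuple[float, float]:
        """(reference volume, penalty coefficient) for an element type."""
        e = self._elem(element)
        return e["vref"], e["solv_coeff"]

    def is_donor(self, atom_name: str) -> bool:
        return atom_name.upper() in self.donor_names

    def is_acceptor(self, atom_name: str, element: str) -> bool:
        return (element.upper() in self.acceptor_elements
                or atom_name.upper() in self.acceptor_names)


# ---------------------------------------------------------------------------
# The five terms


def lj_energy(ff: ForceFieldTables, elem_i: str, elem_j: str, r: float) -> float:
    """12-6 van der Waals: E = ε[(R0/r)¹² − 2(R0/r)⁶], minimum −ε at r = R0."""
    if r <= 0:
        raise ValueError("r must be > 0")
    if r < R_MIN_FLOOR:
        return ff.clash_cap
    r0i, ei = ff.lj_params(elem_i)
    r0j, ej = ff.lj_params(elem_j)
    r0 = 0.5 * (r0i + r0j)
    eps = math.sqrt(ei * ej)
    q = (r0 / r) ** 6
    return min(eps * (q * q - 2.0 * q), ff.clash_cap)


def hbond_energy(ff: ForceFieldTables, donor_name: str, acceptor_name: str,
                 acceptor_element: str, r_da: float,
                 theta_dha_deg: float = 180.0, strict: bool = False) -> float:
    """Hybrid 12-10 hydrogen bond with an angular factor.

    E = D0·[5(R0/R)¹² − 6(R0/R)¹⁰]·F(θ_DHA) with D0 = 8.0 kcal/mol and
    R0 = 2.8 Å; F = cos⁴θ, zero for θ_DHA < 90°.  With no explicit hydrogen
    an ideal linear geometry (F = 1) is assumed.
    """
    if not (ff.is_donor(donor_name)
            and ff.is_acceptor(acceptor_name, acceptor_element)):
        if strict:
            warnings.warn(f"{donor_name}->{acceptor_name} is not a donor/acceptor pair")
        return 0.0
    if r_da <= 0:
        raise ValueError("r_da must be > 0")
    if theta_dha_deg < 90.0:
        return 0.0
    if r_da < R_MIN_FLOOR:
        return ff.clash_cap
    q = ff.hbond_r0 / r_da
    radial = ff.hbond_d0 * (5.0 * q ** 12 - 6.0 * q ** 10)
    angular = math.cos(math.radians(theta_dha_deg)) ** 4
    return min(radial * angular, ff.clash_cap)


def coulomb_energy(ff: ForceFieldTables, q_i: float, q_j: float, r: float) -> float:
    """Coulomb term with distance-dependent dielectric ε(r) = 10·r by default."""
    if r <= 0:
        raise ValueError("r must be > 0")
    if q_i == 0.0 or q_j == 0.0:
        return 0.0
    if r < R_MIN_FLOOR:
        return ff.clash_cap if q_i * q_j > 0 else -ff.clash_cap
    if ff.dielectric_model == "distance_dependent":
        eps_r = ff.dielectric * r
    else:
        eps_r = ff.dielectric
    e = COULOMB_CONSTANT * q_i * q_j / (eps_r * r)
    return max(min(e, ff.clash_cap), -ff.clash_cap)


def solvation_kernel(ff: ForceFieldTables, r: float) -> float:
    return math.exp(-(r / ff.solv_length) ** 2)


def solvation_penalty(ff: ForceFieldTables, element: str,
                      neighbor_elements_distances) -> float:
    """Occlusion-based solvation penalty for one atom.

    penalty = c_type(atom) × Σ_neighbors V_ref(neighbor)·exp(−(r/λ)²) —
    monotone non-decreasing as any neighbor approaches, zero for an isolated
    atom, and pairwise-decomposable.
    """
    _, coeff = ff.solvation_params(element)
    total = 0.0
    for elem_n, r in neighbor_elements_distances:
        vref, _ = ff.solvation_params(elem_n)
        total += vref * solvation_kernel(ff, r)
    return coeff * total


def solvation_pair(ff: ForceFieldTables, elem_i: str, elem_j: str, r: float) -> float:
    """Symmetric pairwise share of the occlusion penalty for atoms i and j."""
    vi, ci = ff.solvation_params(elem_i)
    vj, cj = ff.solvation_params(elem_j)
    k = solvation_kernel(ff, r)
    return ci * vj * k + cj * vi * k


def assign_ss_class(phi: float | None, psi: float | None) -> str:
    """Coarse secondary-structure class from backbone dihedrals."""
    if phi is None or psi is None:
        return "other"
    if -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0:
        return "helix"
    if -180.0 <= phi <= -80.0 and (80.0 <= psi <= 180.0 or -180.0 <= psi <= -170.0):
        return "strand"
    return "other"


def ss_propensity(ff: ForceFieldTables, residue_type: str, ss_class: str) -> float:
    """Position-additive secondary-structure propensity lookup (kcal/mol)."""
    table = ff.ss_table.get(ss_class)
    if table is None:
        raise ValueError(f"unknown secondary-structure class {ss_class!r}")
    res = residue_type.upper()
    if res not in table:
        warnings.warn(f"no {ss_class} propensity entry for {res}; using 0")
        return 0.0
    return table[res]


def pair_term_energy(ff: ForceFieldTables, name_i: str, elem_i: str, xyz_i,
                     name_j: str, elem_j: str, xyz_j) -> float:
    """Sum of the four distance-based terms for one atom pair (cutoff applied)."""
    r = float(np.linalg.norm(np.asarray(xyz_i, float) - np.asarray(xyz_j, float)))
    if r > ff.cutoff:
        return 0.0
    if r < R_MIN_FLOOR:
        return ff.clash_cap
    e = lj_energy(ff, elem_i, elem_j, r)
    e += coulomb_energy(ff, ff.charge(name_i), ff.charge(name_j), r)
    e += solvation_pair(ff, elem_i, elem_j, r)
    if r <= ff.hbond_max:
        if ff.is_donor(name_i) and ff.is_acceptor(name_j, elem_j):
            e += hbond_energy(ff, name_i, name_j, elem_j, r)
        elif ff.is_donor(name_j) and ff.is_acceptor(name_i, elem_i):
            e += hbond_energy(ff, name_j, name_i, elem_i, r)
    return min(e, ff.clash_cap)


# ---------------------------------------------------------------------------
# Energy matrices


@dataclass(frozen=True)
class Choice:
    """One (amino acid, rotamer) option at a designed position."""
    aa: str
    rotamer_id: int
    chi: tuple[float, ...] = ()


@dataclass
class EnergyMatrices:
    """Singles and pairs energies over per-position (aa, rotamer) choices.

    ``singles[i][r]`` is the rotamer↔template energy of choice r at position
    i (kcal/mol, secondary-structure propensity included); ``pairs[(i, j)]``
    with i < j is the rotamer↔rotamer matrix.  The template↔template
    constant is excluded.
    """

    positions: list
    choices: list[list[Choice]]
    singles: list[np.ndarray]
    pairs: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.choices) != len(self.singles):
            raise ValueError("positions/choices/singles length mismatch")
        for (i, j) in self.pairs:
            if not i < j:
                raise ValueError("pair keys must satisfy i < j")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def n_choices(self, i: int) -> int:
        return len(self.choices[i])

    def pair(self, i: int, r: int, j: int, s: int) -> float:
        """Symmetric pair access: pair(i_r, j_s) = pair(j_s, i_r)."""
        if i == j:
            raise ValueError("pair energies are defined for distinct positions")
        if i > j:
            i, j, r, s = j, i, s, r
        m = self.pairs.get((i, j))
        return 0.0 if m is None else float(m[r, s])

    def assignment_energy(self, assignment) -> float:
        """E = Σ_i singles + Σ_{i<j} pairs for one rotamer per position."""
        e = sum(float(self.singles[i][r]) for i, r in enumerate(assignment))
        n = self.n_positions
        for i in range(n):
            for j in range(i + 1, n):
                e += self.pair(i, assignment[i], j, assignment[j])
        return e

    def restrict(self, allowed_aa_per_position) -> "EnergyMatrices":
        """Sub-matrices keeping only choices whose amino acid is allowed."""
        keep = []
        for i, chs in enumerate(self.choices):
            idx = [r for r, c in enumerate(chs) if c.aa in allowed_aa_per_position[i]]
            if not idx:
                raise ValueError(f"position {self.positions[i]}: no choice left "
                                 f"for {allowed_aa_per_position[i]}")
            keep.append(idx)
        new_choices = [[self.choices[i][r] for r in keep[i]] for i in range(self.n_positions)]
        new_singles = [self.singles[i][keep[i]] for i in range(self.n_positions)]
        new_pairs = {(i, j): m[np.ix_(keep[i], keep[j])] for (i, j), m in self.pairs.items()}
        return EnergyMatrices(list(self.positions), new_choices, new_singles, new_pairs)

    # -- serialization (CSV pair) -----------------------------------------
    def to_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, chs in enumerate(self.choices):
            for r, c in enumerate(chs):
                rows.append({"position_index": i, "position": str(self.positions[i]),
                             "choice": r, "aa": c.aa, "rotamer_id": c.rotamer_id,
                             "energy": float(self.singles[i][r])})
        pd.DataFrame(rows).to_csv(directory / "singles.csv", index=False)
        prows = []
        for (i, j), m in sorted(self.pairs.items()):
            for r in range(m.shape[0]):
                for s in range(m.shape[1]):
                    prows.append({"i": i, "ri": r, "j": j, "rj": s,
                                  "energy": float(m[r, s])})
        pd.DataFrame(prows, columns=["i", "ri", "j", "rj", "energy"]).to_csv(
            directory / "pairs.csv", index=False)

    @classmethod
    def from_csv(cls, directory) -> "EnergyMatrices":
        directory = Path(directory)
        sdf = pd.read_csv(directory / "singles.csv")
        positions, choices, singles = [], [], []
        for i, grp in sdf.groupby("position_index"):
            positions.append(grp["position"].iloc[0])
            choices.append([Choice(row.aa, int(row.rotamer_id))
                            for row in grp.itertuples()])
            singles.append(grp["energy"].to_numpy())
        pairs: dict[tuple[int, int], np.ndarray] = {}
        pdf = pd.read_csv(directory / "pairs.csv")
        for (i, j), grp in pdf.groupby(["i", "j"]):
            m = np.zeros((len(choices[i]), len(choices[j])))
            m[grp["ri"].to_numpy(), grp["rj"].to_numpy()] = grp["energy"].to_numpy()
            pairs[(int(i), int(j))] = m
        return cls(positions, choices, singles, pairs)


def _backbone_dihedrals(chain_residues, idx: int) -> tuple[float | None, float | None]:
    res = chain_residues[idx]
    phi = psi = None
    try:
        if idx > 0:
            prev = chain_residues[idx - 1]
            phi = dihedral(prev.atom("C").coords, res.atom("N").coords,
                           res.atom("CA").coords, res.atom("C").coords)
        if idx + 1 < len(chain_residues):
            nxt = chain_residues[idx + 1]
            psi = dihedral(res.atom("N").coords, res.atom("CA").coords,
                           res.atom("C").coords, nxt.atom("N").coords)
    except KeyError:
        pass
    return phi, psi


_SIDECHAIN_SKIP = {"N", "CA", "C", "O", "OXT", "CB"}


def build_energy_matrices(template: Structure, positions, candidates,
                          ff: ForceFieldTables | None = None) -> EnergyMatrices:
    """Assemble singles/pairs matrices for designed positions on a template.

    ``positions``: list of (chain_id, residue_number).  ``candidates``: per
    position, a list of (aa, χ tuple) side-chain options; side chains are
    built on the template backbone.  Singles sum the pairwise terms between
    rotamer atoms and all template atoms outside the designed residues (plus
    the position-additive propensity term); pairs sum terms between rotamer
    atoms at distinct designed positions.  Clashes are capped, never
    infinite.
    """
    if ff is None:
        ff = ForceFieldTables()
    pos_res = [template.get_residue(c, n) for c, n in positions]
    designed_keys = {(c, n) for c, n in positions}

    # template context: every atom not belonging to a designed residue's
    # side chain (designed backbones beyond the residue itself still count
    # for *other* positions; the own residue is excluded from its singles)
    context = []
    for chain in template.chains:
        for idx, res in enumerate(chain.residues):
            for a in res.atoms:
                if (chain.id, res.number) in designed_keys and a.name not in _SIDECHAIN_SKIP:
                    continue  # replaced side chain
                context.append((a.name, a.element, a.coords, (chain.id, res.number)))
    for res in template.ligands:
        for a in res.atoms:
            context.append((a.name, a.element, a.coords, ("_ligand", res.number)))

    # secondary-structure class per designed position
    ss_classes = []
    for (chain_id, num) in positions:
        for chain in template.chains:
            if chain.id != chain_id:
                continue
            for idx, res in enumerate(chain.residues):
                if res.number == num:
                    ss_classes.append(assign_ss_class(*_backbone_dihedrals(chain.residues, idx)))

    # build rotamer atom sets
    built: list[list[list[tuple[str, str, np.ndarray]] | None]] = []
    choices: list[list[Choice]] = []
    for p, (res, cand) in enumerate(zip(pos_res, candidates)):
        backbone = {n: res.atom(n).coords for n in ("N", "CA", "C") if res.has_atom(n)}
        row_atoms, row_choices = [], []
        for rid, (aa, chi) in enumerate(cand):
            try:
                atoms = build_sidechain(aa, chi, backbone)
            except ValueError as exc:
                warnings.warn(f"position {positions[p]}: unbuildable rotamer "
                              f"{aa}/{rid}: {exc}; excluded")
                continue
            row_atoms.append(atoms)
            row_choices.append(Choice(aa, rid, tuple(chi)))
        if not row_choices:
            raise ValueError(f"position {positions[p]}: no buildable rotamer")
        built.append(row_atoms)
        choices.append(row_choices)

    singles = []
    for p, (key, row) in enumerate(zip(positions, built)):
        vals = np.zeros(len(row))
        for r, atoms in enumerate(row):
            e = ss_propensity(ff, choices[p][r].aa, ss_classes[p])
            for (an, ae, axyz) in atoms:
                for (tn, te, txyz, tkey) in context:
                    if tkey == key:
                        continue  # own residue (bonded context) excluded
                    e += pair_term_energy(ff, an, ae, axyz, tn, te, txyz)
            vals[r] = min(e, ff.clash_cap)
        singles.append(vals)

    pairs: dict[tuple[int, int], np.ndarray] = {}
    n = len(positions)
    for i in range(n):
        for j in range(i + 1, n):
            m = np.zeros((len(built[i]), len(built[j])))
            for r, atoms_i in enumerate(built[i]):
                for s, atoms_j in enumerate(built[j]):
                    e = 0.0
                    for (an, ae, axyz) in atoms_i:
                        for (bn, be, bxyz) in atoms_j:
                            e += pair_term_energy(ff, an, ae, axyz, bn, be, bxyz)
                    m[r, s] = min(e, ff.clash_cap)
            if np.any(m != 0.0):
                pairs[(i, j)] = m
    return EnergyMatrices(list(positions), choices, singles, pairs)
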
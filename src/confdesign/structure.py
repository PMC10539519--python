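"""Coordinate-file model, atom selection, superposition and RMSD.

The in-memory model is a light hierarchy (Structure → Chain → Residue →
AtomRecord) holding author numbering and Cartesian coordinates in Å.  PDB
reading and writing are backed by :mod:`gemmi`; the policies layered on top
(alternate-location collapse, water filtering, separation of HETATM cofactors
into a ligand group) are applied after parsing.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import gemmi
import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "Structure",
    "AtomSelection",
    "RigidTransform",
    "PDBParseError",
    "TopologyError",
    "read_pdb",
    "write_pdb",
    "superpose",
    "rmsd_between",
]


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class TopologyError(ValueError):
    """Raised when two structures do not share topology over a selection."""


@dataclass
class AtomRecord:
    """A single atom with PDB-style metadata, coordinates in Å."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str = ""
    alt_loc: str = ""
    occupancy: float = 1.0
    coords: np.ndarray = field(default_factory=lambda: np.zeros(3))
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    name: str
    number: int
    insertion_code: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.number}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def key(self) -> tuple[str, int, str]:
        chain = self.atoms[0].chain_id if self.atoms else ""
        return (chain, self.number, self.insertion_code)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Structure:
    """A protein structure: ordered chains of residues plus a ligand group."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    ligands: list[Residue] = field(default_factory=list)
    numbering_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for chain in self.chains:
            for res in chain.residues:
                key = (chain.id, res.number, res.insertion_code)
                if key in seen:
                    raise ValueError(f"duplicate residue {key}")
                seen.add(key)

    # -- iteration helpers -------------------------------------------------
    def iter_residues(self):
        for chain in self.chains:
            for res in chain.residues:
                yield chain.id, res

    def iter_atoms(self, include_ligands: bool = True):
        for _, res in self.iter_residues():
            yield from res.atoms
        if include_ligands:
            for res in self.ligands:
                yield from res.atoms

    def get_residue(self, chain_id: str, number: int, icode: str = "") -> Residue:
        for chain in self.chains:
            if chain.id != chain_id:
                continue
            for res in chain.residues:
                if res.number == number and res.insertion_code == icode:
                    return res
        raise KeyError(f"no residue {chain_id}:{number}{icode}")

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def coords_array(self, include_ligands: bool = True) -> np.ndarray:
        return np.array([a.coords for a in self.iter_atoms(include_ligands)])

    def set_coords_array(self, xyz: np.ndarray, include_ligands: bool = True) -> None:
        atoms = list(self.iter_atoms(include_ligands))
        xyz = np.asarray(xyz, dtype=float).reshape(len(atoms), 3)
        for a, row in zip(atoms, xyz):
            a.coords = row.copy()

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


@dataclass
class AtomSelection:
    """Chain / residue-range / atom-class filter.

    ``atom_class`` is one of ``"heavy"`` (all non-hydrogen), ``"backbone"``
    (N, CA, C, O) or ``"ca"``.  ``residue_ranges`` is a list of inclusive
    (start, stop) author-number pairs; empty means all residues.
    String form (CLI/config): ``"A:355-365:CA"``, ``":1-10,20-30:backbone"``,
    ``"A::heavy"``.
    """

    chain_id: str | None = None
    residue_ranges: list[tuple[int, int]] = field(default_factory=list)
    atom_class: str = "heavy"

    def __post_init__(self) -> None:
        if self.atom_class not in ("heavy", "backbone", "ca"):
            raise ValueError(f"unknown atom class {self.atom_class!r}")

    @classmethod
    def parse(cls, text: str) -> "AtomSelection":
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"selection {text!r}: expected 'chain:ranges:class'")
        chain = parts[0] or None
        ranges = []
        if parts[1]:
            for span in parts[1].split(","):
                lo, _, hi = span.partition("-")
                ranges.append((int(lo), int(hi) if hi else int(lo)))
        return cls(chain, ranges, (parts[2] or "heavy").lower())

    def _residue_ok(self, chain_id: str, res: Residue) -> bool:
        if self.chain_id is not None and chain_id != self.chain_id:
            return False
        if not self.residue_ranges:
            return True
        return any(lo <= res.number <= hi for lo, hi in self.residue_ranges)

    def _atom_ok(self, atom: AtomRecord) -> bool:
        if self.atom_class == "ca":
            return atom.name == "CA"
        if self.atom_class == "backbone":
            return atom.name in BACKBONE_ATOMS
        return not atom.is_hydrogen

    def apply(self, s: Structure) -> list[AtomRecord]:
        out = []
        for chain_id, res in s.iter_residues():
            if self._residue_ok(chain_id, res):
                out.extend(a for a in res.atoms if self._atom_ok(a))
        return out


@dataclass
class RigidTransform:
    """Proper rotation + translation; y = R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthogonal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.rotation.T + self.translation

    def apply_to_structure(self, s: Structure) -> Structure:
        out = s.copy()
        out.set_coords_array(self.apply(out.coords_array()))
        return out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: first apply *other*, then *self*."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


# ---------------------------------------------------------------------------
# PDB I/O

_WATER_NAMES = {"HOH", "WAT", "DOD"}
_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _collapse_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties by alt-loc."""
    best: dict[str, AtomRecord] = {}
    for a in atoms:
        cur = best.get(a.name)
        if cur is None or (a.occupancy, _neg_ord(a.alt_loc)) > (cur.occupancy, _neg_ord(cur.alt_loc)):
            best[a.name] = a
    out = []
    seen = set()
    for a in atoms:  # preserve original atom order
        if a.name not in seen and best[a.name] is a:
            out.append(a)
            seen.add(a.name)
        elif a.name not in seen and best[a.name] is not a:
            out.append(best[a.name])
            seen.add(a.name)
    for a in out:
        a.alt_loc = ""
    return out


def _neg_ord(alt: str) -> int:
    # alphabetically earlier alt-loc wins ties → higher sort key
    return -ord(alt) if alt else 0


def read_pdb(path, alt_loc_policy: str = "occupancy", keep_waters: bool = False) -> Structure:
    """Read a fixed-column PDB file into a :class:`Structure`.

    Protein residues go into chains; HETATM cofactors (e.g. PLP) are retained
    in ``structure.ligands``; waters are discarded unless ``keep_waters``.
    ``alt_loc_policy``: ``"occupancy"`` (default, keep highest-occupancy
    conformer, ties broken alphabetically) or ``"first"``.
    """
    if alt_loc_policy not in ("occupancy", "first"):
        raise ValueError(f"unknown alt_loc_policy {alt_loc_policy!r}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise PDBParseError(f"{path}: no atoms found")

    model = st[0]
    chains: list[Chain] = []
    ligands: list[Residue] = []
    serial = 0
    for gchain in model:
        chain = Chain(id=gchain.name.strip() or "A")
        for gres in gchain:
            name = gres.name.strip()
            if name in _WATER_NAMES and not keep_waters:
                continue
            atoms = []
            for gatom in gres:
                serial += 1
                atoms.append(AtomRecord(
                    serial=serial,
                    name=gatom.name.strip(),
                    element=gatom.element.name,
                    residue_name=name,
                    chain_id=chain.id,
                    residue_number=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    alt_loc=(gatom.altloc or "").strip(),
                    occupancy=min(max(gatom.occ, 0.0), 1.0),
                    coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    b_factor=gatom.b_iso,
                ))
            if alt_loc_policy == "occupancy":
                atoms = _collapse_altlocs(atoms)
            else:
                seen: set[str] = set()
                kept = []
                for a in atoms:
                    if a.name not in seen:
                        kept.append(a)
                        seen.add(a.name)
                        a.alt_loc = ""
                atoms = kept
            res = Residue(name=name, number=gres.seqid.num,
                          insertion_code=(gres.seqid.icode or "").strip(), atoms=atoms)
            if name in _AA3 and gres.het_flag != "H":
                chain.residues.append(res)
            elif name in _AA3:
                chain.residues.append(res)  # HETATM-coded standard residue
            else:
                ligands.append(res)
        if chain.residues:
            chains.append(chain)
    return Structure(id=str(getattr(st, "name", "") or path), chains=chains, ligands=ligands)


def write_pdb(s: Structure, path) -> None:
    """Write *s* as fixed-column PDB (8.3 coordinate fields)."""
    lines = []
    serial = 0
    for chain in s.chains:
        for res in chain.residues:
            for a in res.atoms:
                serial += 1
                lines.append(_atom_line("ATOM", serial, a, res, chain.id))
        serial += 1
        last = chain.residues[-1]
        lines.append(f"TER   {serial:5d}      {last.name:>3s} {chain.id:1s}{last.number:4d}")
    for res in s.ligands:
        for a in res.atoms:
            serial += 1
            lines.append(_atom_line("HETATM", serial, a, res, a.chain_id or "A"))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _atom_line(record: str, serial: int, a: AtomRecord, res: Residue, chain_id: str) -> str:
    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
    x, y, z = a.coords
    return (f"{record:<6s}{serial:5d} {name:<4s}{a.alt_loc or ' ':1s}{res.name:>3s} "
            f"{chain_id:1s}{res.number:4d}{res.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
            f"          {a.element:>2s}")


# ---------------------------------------------------------------------------
# Superposition and RMSD


def _matched_coords(a: Structure, b: Structure, sel: AtomSelection) -> tuple[np.ndarray, np.ndarray]:
    atoms_a = sel.apply(a)
    atoms_b = sel.apply(b)
    if len(atoms_a) != len(atoms_b):
        raise TopologyError(
            f"selection matches {len(atoms_a)} atoms in {a.id} but {len(atoms_b)} in {b.id}")
    for xa, xb in zip(atoms_a, atoms_b):
        if (xa.name, xa.residue_number) != (xb.name, xb.residue_number):
            raise TopologyError(
                f"first unmatched atom: {xa.chain_id}:{xa.residue_number}:{xa.name} vs "
                f"{xb.chain_id}:{xb.residue_number}:{xb.name}")
    return (np.array([x.coords for x in atoms_a]),
            np.array([x.coords for x in atoms_b]))


def kabsch(mobile_xyz: np.ndarray, ref_xyz: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares proper rotation + translation mapping mobile onto ref.

    Standard SVD solution with reflection correction, so the returned rotation
    always has determinant +1 even for mirrored inputs.
    """
    P = np.asarray(mobile_xyz, dtype=float)
    Q = np.asarray(ref_xyz, dtype=float)
    if P.shape[0] < 3:
        raise ValueError(f"need ≥3 matched atoms, got {P.shape[0]}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    # collinearity check: rank of the centered mobile set
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise ValueError("degenerate geometry: matched atoms are collinear")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    tr = RigidTransform(R, t)
    diff = tr.apply(P) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / P.shape[0]))
    return tr, rmsd


def superpose(mobile: Structure, reference: Structure,
              sel: AtomSelection | str | None = None) -> tuple[RigidTransform, float]:
    """Superpose *mobile* onto *reference* over a selection (Kabsch).

    Returns the proper rigid transform and the post-fit RMSD in Å.
    """
    if sel is None:
        sel = AtomSelection()
    elif isinstance(sel, str):
        sel = AtomSelection.parse(sel)
    P, Q = _matched_coords(mobile, reference, sel)
    return kabsch(P, Q)


def rmsd_between(a: Structure, b: Structure, sel: AtomSelection | str | None = None,
                 fit: bool = True) -> float:
    """RMSD between matched atoms of two structures, optionally after fitting."""
    if sel is None:
        sel = AtomSelection()
    elif isinstance(sel, str):
        sel = AtomSelection.parse(sel)
    P, Q = _matched_coords(a, b, sel)
    if fit:
        _, rmsd = kabsch(P, Q)
        return rmsd
    diff = P - Q
    return float(np.sqrt((diff ** 2).sum() / P.shape[0]))
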
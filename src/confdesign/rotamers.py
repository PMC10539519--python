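"""Backbone-dependent rotamer library handling and side-chain construction.

The reader accepts the 2002-style backbone-dependent rotamer library text
format (whitespace columns: residue, φ, ψ, count, r1–r4, probability, four χ
means, four χ standard deviations).  A small synthetic library covering all
18 designable side-chain-bearing types (proline excluded from design; glycine
is rotamer-free) is bundled for tests and toy runs.

χ-expansion follows the ±1σ scheme around χ1 and χ2: a rotamer with one χ
angle expands to 3 variants, one with two or more to 9 (χ3/χ4 stay at their
means).

Side chains are built on a backbone by sequential torsion (NeRF) construction
with ideal bond lengths and angles, so re-measuring χ from built coordinates
returns the inputs exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "RotamerRecord",
    "RotamerLibrary",
    "load_rotamer_library",
    "bundled_library_path",
    "build_sidechain",
    "measure_chis",
    "dihedral",
    "place_atom",
    "CHI_DEFS",
    "DESIGN_ALPHABET",
]

# χ dihedral atom quadruples, in order χ1..χ4.
CHI_DEFS: dict[str, list[tuple[str, str, str, str]]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
}

# All proteinogenic amino acids except proline (excluded from design).
DESIGN_ALPHABET = tuple(sorted(CHI_DEFS))  # 19 types


@dataclass(frozen=True)
class RotamerRecord:
    residue_type: str
    phi: float          # backbone bin, degrees
    psi: float
    probability: float
    chi: tuple[float, ...]      # means, degrees, length = nχ of the type
    chi_sd: tuple[float, ...]

    def __post_init__(self):
        for c in self.chi:
            if not -180.0 < c <= 180.0:
                raise ValueError(f"χ {c} outside (−180, 180]")
        if any(s < 0 for s in self.chi_sd):
            raise ValueError("χ standard deviation must be ≥ 0")

    def expand(self) -> list[tuple[float, ...]]:
        """±1σ expansion around χ1 and χ2: 3^min(nχ,2) variants."""
        if not self.chi:
            return [()]
        variants: list[list[float]] = [[]]
        for k, (mean, sd) in enumerate(zip(self.chi, self.chi_sd)):
            opts = [mean - sd, mean, mean + sd] if k < 2 else [mean]
            variants = [v + [_wrap(o)] for v in variants for o in opts]
        return [tuple(v) for v in variants]


def _wrap(angle: float) -> float:
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


class RotamerLibrary:
    """Backbone-dependent lookup (residue type, φ, ψ) → rotamers."""

    def __init__(self, records: list[RotamerRecord], expand: bool = False):
        self.records = records
        self.expand_flag = expand
        self._by_type: dict[str, dict[tuple[float, float], list[RotamerRecord]]] = {}
        for r in records:
            self._by_type.setdefault(r.residue_type, {}).setdefault((r.phi, r.psi), []).append(r)

    def lookup(self, residue_type: str, phi: float, psi: float) -> list[RotamerRecord]:
        """Rotamers from the nearest available (φ, ψ) bin for the type."""
        if residue_type in ("ALA", "GLY"):
            return []
        bins = self._by_type.get(residue_type)
        if not bins:
            raise KeyError(f"no rotamers for residue type {residue_type}")
        key = min(bins, key=lambda b: _ang_dist(b[0], phi) + _ang_dist(b[1], psi))
        return bins[key]

    def chi_variants(self, residue_type: str, phi: float, psi: float) -> list[tuple[float, ...]]:
        """All χ tuples for the type at this backbone, ±1σ-expanded if enabled.

        ALA and GLY yield a single empty tuple (one rotamer-free choice).
        """
        if residue_type in ("ALA", "GLY"):
            return [()]
        out: list[tuple[float, ...]] = []
        for rec in self.lookup(residue_type, phi, psi):
            out.extend(rec.expand() if self.expand_flag else [rec.chi])
        return out


def _ang_dist(a: float, b: float) -> float:
    return abs(_wrap(a - b))


def load_rotamer_library(path=None, expand: bool = False) -> RotamerLibrary:
    """Read a Dunbrack-style whitespace-column rotamer library.

    Expected columns: res φ ψ count r1 r2 r3 r4 prob χ1 χ2 χ3 χ4 σ1 σ2 σ3 σ4.
    χ columns beyond the type's nχ are ignored.  With ``path=None`` the
    bundled synthetic mini-library is used.
    """
    if path is None:
        path = bundled_library_path()
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 17:
                raise ValueError(f"{path}:{lineno}: expected 17 columns, got {len(parts)}")
            res = parts[0].upper()
            if res not in CHI_DEFS:
                continue
            nchi = len(CHI_DEFS[res])
            try:
                phi, psi = float(parts[1]), float(parts[2])
                prob = float(parts[8])
                chis = tuple(_wrap(float(x)) for x in parts[9:9 + nchi])
                sds = tuple(float(x) for x in parts[13:13 + nchi])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if nchi:
                records.append(RotamerRecord(res, phi, psi, prob, chis, sds))
    if not records:
        raise ValueError(f"{path}: no rotamer records parsed")
    return RotamerLibrary(records, expand=expand)


def bundled_library_path():
    return resources.files("confdesign").joinpath("data/mini_rotamers.lib")


# ---------------------------------------------------------------------------
# Geometry: torsion construction and measurement


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place a new atom bonded to *c* given bond / angle(b,c,new) / torsion(a,b,c,new)."""
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(theta),
                  bond * math.sin(theta) * math.cos(phi),
                  -bond * math.sin(theta) * math.sin(phi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (−180, 180]."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return _wrap(math.degrees(math.atan2(y, x)))


# Side-chain internal-coordinate templates.  Each atom: (name, element,
# (ref_a, ref_b, ref_c), bond Å, angle(ref_b, ref_c, atom) deg, torsion spec).
# A torsion spec is either a fixed float (degrees) or ("chi", k, offset):
# χ_k + offset.  CB is shared by all non-Gly types.
_CB = ("CB", "C", ("N", "C", "CA"), 1.530, 110.5, 122.68)

_TEMPLATES: dict[str, list] = {
    "ALA": [],
    "GLY": None,
    "SER": [("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 1, 0.0))],
    "CYS": [("SG", "S", ("N", "CA", "CB"), 1.808, 113.8, ("chi", 1, 0.0))],
    "THR": [("OG1", "O", ("N", "CA", "CB"), 1.433, 109.6, ("chi", 1, 0.0)),
            ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -120.0))],
    "VAL": [("CG1", "C", ("N", "CA", "CB"), 1.527, 110.5, ("chi", 1, 0.0)),
            ("CG2", "C", ("N", "CA", "CB"), 1.527, 110.5, ("chi", 1, 122.3))],
    "LEU": [("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1, 0.0)),
            ("CD1", "C", ("CA", "CB", "CG"), 1.524, 110.7, ("chi", 2, 0.0)),
            ("CD2", "C", ("CA", "CB", "CG"), 1.524, 110.7, ("chi", 2, 122.5))],
    "ILE": [("CG1", "C", ("N", "CA", "CB"), 1.530, 110.4, ("chi", 1, 0.0)),
            ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -122.3)),
            ("CD1", "C", ("CA", "CB", "CG1"), 1.513, 113.9, ("chi", 2, 0.0))],
    "MET": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
            ("SD", "S", ("CA", "CB", "CG"), 1.807, 112.7, ("chi", 2, 0.0)),
            ("CE", "C", ("CB", "CG", "SD"), 1.789, 100.7, ("chi", 3, 0.0))],
    "ASP": [("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
            ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 0.0)),
            ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 180.0))],
    "ASN": [("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
            ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, ("chi", 2, 0.0)),
            ("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, ("chi", 2, 180.0))],
    "GLU": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2, 0.0)),
            ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 0.0)),
            ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 180.0))],
    "GLN": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2, 0.0)),
            ("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, ("chi", 3, 0.0)),
            ("NE2", "N", ("CB", "CG", "CD"), 1.328, 116.4, ("chi", 3, 180.0))],
    "LYS": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
            ("CE", "C", ("CB", "CG", "CD"), 1.520, 111.3, ("chi", 3, 0.0)),
            ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.9, ("chi", 4, 0.0))],
    "ARG": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
            ("NE", "N", ("CB", "CG", "CD"), 1.461, 112.0, ("chi", 3, 0.0)),
            ("CZ", "C", ("CG", "CD", "NE"), 1.329, 124.2, ("chi", 4, 0.0)),
            ("NH1", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
            ("NH2", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0)],
    "HIS": [("CG", "C", ("N", "CA", "CB"), 1.500, 113.8, ("chi", 1, 0.0)),
            ("ND1", "N", ("CA", "CB", "CG"), 1.378, 122.7, ("chi", 2, 0.0)),
            ("CD2", "C", ("CA", "CB", "CG"), 1.356, 131.0, ("chi", 2, 180.0)),
            ("CE1", "C", ("CB", "CG", "ND1"), 1.320, 109.3, 180.0),
            ("NE2", "N", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0)],
    "PHE": [("CG", "C", ("N", "CA", "CB"), 1.500, 113.8, ("chi", 1, 0.0)),
            ("CD1", "C", ("CA", "CB", "CG"), 1.391, 120.8, ("chi", 2, 0.0)),
            ("CD2", "C", ("CA", "CB", "CG"), 1.391, 120.8, ("chi", 2, 180.0)),
            ("CE1", "C", ("CB", "CG", "CD1"), 1.393, 120.8, 180.0),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.393, 120.8, 180.0),
            ("CZ", "C", ("CG", "CD1", "CE1"), 1.390, 120.0, 0.0)],
    "TYR": [("CG", "C", ("N", "CA", "CB"), 1.500, 113.8, ("chi", 1, 0.0)),
            ("CD1", "C", ("CA", "CB", "CG"), 1.391, 120.8, ("chi", 2, 0.0)),
            ("CD2", "C", ("CA", "CB", "CG"), 1.391, 120.8, ("chi", 2, 180.0)),
            ("CE1", "C", ("CB", "CG", "CD1"), 1.393, 120.8, 180.0),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.393, 120.8, 180.0),
            ("CZ", "C", ("CG", "CD1", "CE1"), 1.390, 120.0, 0.0),
            ("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0)],
    "TRP": [("CG", "C", ("N", "CA", "CB"), 1.500, 113.6, ("chi", 1, 0.0)),
            ("CD1", "C", ("CA", "CB", "CG"), 1.365, 126.9, ("chi", 2, 0.0)),
            ("CD2", "C", ("CA", "CB", "CG"), 1.433, 126.6, ("chi", 2, 180.0)),
            ("NE1", "N", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
            ("CE3", "C", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
            ("CZ2", "C", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
            ("CZ3", "C", ("CG", "CD2", "CE3"), 1.392, 118.6, 180.0),
            ("CH2", "C", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0.0)],
}


def build_sidechain(residue_type: str, chi: tuple[float, ...] | list[float],
                    backbone: dict[str, np.ndarray]) -> list[tuple[str, str, np.ndarray]]:
    """Build side-chain atoms (CB outward) on a backbone.

    ``backbone`` must provide N, CA, C coordinates.  Returns a list of
    (atom name, element, coordinates); empty for glycine.  Deterministic and
    χ-exact: re-measuring any χ_k from the built coordinates returns the
    input value.
    """
    residue_type = residue_type.upper()
    if residue_type not in _TEMPLATES:
        raise ValueError(f"no side-chain template for {residue_type}")
    for name in ("N", "CA", "C"):
        if name not in backbone:
            raise ValueError(f"missing backbone atom {name}")
    if residue_type == "GLY":
        return []
    nchi = len(CHI_DEFS[residue_type])
    chi = tuple(chi)
    if len(chi) != nchi:
        raise ValueError(f"{residue_type} needs {nchi} χ angles, got {len(chi)}")

    coords: dict[str, np.ndarray] = {k: np.asarray(v, dtype=float) for k, v in backbone.items()}
    built: list[tuple[str, str, np.ndarray]] = []

    def _place(name, element, refs, bond, angle, torsion):
        pos = place_atom(coords[refs[0]], coords[refs[1]], coords[refs[2]],
                         bond, angle, torsion)
        coords[name] = pos
        built.append((name, element, pos))

    name, element, refs, bond, angle, torsion = _CB
    _place(name, element, refs, bond, angle, torsion)
    for name, element, refs, bond, angle, tspec in _TEMPLATES[residue_type]:
        if isinstance(tspec, tuple):
            _, k, offset = tspec
            torsion = chi[k - 1] + offset
        else:
            torsion = tspec
        _place(name, element, refs, bond, angle, torsion)
    return built


def measure_chis(residue_type: str, coords: dict[str, np.ndarray]) -> tuple[float, ...]:
    """Measure χ angles from a coordinate dict covering the χ-defining atoms."""
    out = []
    for quad in CHI_DEFS[residue_type.upper()]:
        try:
            pts = [np.asarray(coords[n], dtype=float) for n in quad]
        except KeyError as exc:
            raise ValueError(f"missing atom {exc} for χ of {residue_type}") from exc
        out.append(dihedral(*pts))
    return tuple(out)
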
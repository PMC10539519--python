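"""Hinge-mediated domain motion between two conformations.

Given open and closed structures and a user-supplied domain partition
(fixed / moving / hinge residues), quantifies the inter-domain motion as a
screw: rotation angle, axis direction, a point on the axis, and the
axis-parallel translation.  Also computes per-residue Cα displacement
statistics for a target segment after a fixed-domain fit.

Automatic domain decomposition (DynDom-style clustering of local rotation
vectors) is deliberately not implemented; partitions come from the user or a
config block, because the downstream design logic only needs the geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .structure import AtomSelection, RigidTransform, Structure, kabsch

ANGLE_FLOOR_DEG = 1e-4

__all__ = ["DomainPartition", "HingeMotion", "domain_rotation", "ca_displacement_stats"]


@dataclass
class DomainPartition:
    """Disjoint residue sets defining fixed domain, moving domain and hinge."""

    fixed_domain: frozenset
    moving_domain: frozenset
    hinge_residues: frozenset = frozenset()
    chain_id: str | None = None

    def __post_init__(self) -> None:
        self.fixed_domain = frozenset(self.fixed_domain)
        self.moving_domain = frozenset(self.moving_domain)
        self.hinge_residues = frozenset(self.hinge_residues)
        sets = [self.fixed_domain, self.moving_domain, self.hinge_residues]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("partition sets must be pairwise disjoint")
        if len(self.fixed_domain) < 3 or len(self.moving_domain) < 3:
            raise ValueError("fixed and moving domains each need ≥3 residues")

    @classmethod
    def from_ranges(cls, fixed: list[tuple[int, int]], moving: list[tuple[int, int]],
                    hinge: list[tuple[int, int]] | None = None,
                    chain_id: str | None = None) -> "DomainPartition":
        expand = lambda ranges: frozenset(
            n for lo, hi in (ranges or []) for n in range(lo, hi + 1))
        return cls(expand(fixed), expand(moving), expand(hinge), chain_id)

    @classmethod
    def from_yaml(cls, path) -> "DomainPartition":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        to_ranges = lambda spans: [tuple(map(int, str(s).split("-"))) if "-" in str(s)
                                   else (int(s), int(s)) for s in spans]
        return cls.from_ranges(to_ranges(cfg["fixed"]), to_ranges(cfg["moving"]),
                               to_ranges(cfg.get("hinge", [])), cfg.get("chain"))

    def selection(self, domain: str) -> AtomSelection:
        numbers = sorted(getattr(self, domain))
        ranges = _collapse_ranges(numbers)
        return AtomSelection(chain_id=self.chain_id, residue_ranges=ranges, atom_class="ca")


def _collapse_ranges(numbers: list[int]) -> list[tuple[int, int]]:
    ranges: list[tuple[int, int]] = []
    for n in numbers:
        if ranges and n == ranges[-1][1] + 1:
            ranges[-1] = (ranges[-1][0], n)
        else:
            ranges.append((n, n))
    return ranges


@dataclass
class HingeMotion:
    """Screw description of a domain motion plus per-residue Cα displacements."""

    rotation_angle: float          # degrees, in [0, 180]
    screw_axis: np.ndarray | None  # unit direction, None when null
    axis_point: np.ndarray | None  # a point on the axis, Å
    axis_translation: float        # translation along the axis, Å
    null_axis: bool = False
    per_residue_ca_displacement: dict[int, float] = field(default_factory=dict)


def _rotation_angle_axis(R: np.ndarray) -> tuple[float, np.ndarray | None]:
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = float(np.degrees(np.arccos(cos_theta)))
    if theta < ANGLE_FLOOR_DEG:
        return theta, None
    # axis: real eigenvector of R for eigenvalue 1
    w, v = np.linalg.eig(R)
    idx = int(np.argmin(np.abs(w - 1.0)))
    axis = np.real(v[:, idx])
    axis /= np.linalg.norm(axis)
    # orient axis so the rotation about it is positive (right-handed)
    skew = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if theta < 179.999 and np.dot(skew, axis) < 0:
        axis = -axis
    return theta, axis


def domain_rotation(open_s: Structure, closed_s: Structure,
                    part: DomainPartition) -> HingeMotion:
    """Rotation of the moving domain relative to the fixed domain.

    Both structures are first superposed on fixed-domain Cα atoms; the
    residual transform carrying the open moving domain onto the closed one is
    decomposed into screw form (angle from the trace of the rotation matrix,
    axis as its unit eigenvector, translation as the axis-parallel component
    of the residual translation).
    """
    fixed_sel = part.selection("fixed_domain")
    tr_fixed, _ = kabsch(
        np.array([a.coords for a in fixed_sel.apply(closed_s)]),
        np.array([a.coords for a in fixed_sel.apply(open_s)]))
    closed_aligned = tr_fixed.apply_to_structure(closed_s)

    moving_sel = part.selection("moving_domain")
    P = np.array([a.coords for a in moving_sel.apply(open_s)])
    Q = np.array([a.coords for a in moving_sel.apply(closed_aligned)])
    tr_move, _ = kabsch(P, Q)
    R, t = tr_move.rotation, tr_move.translation

    theta, axis = _rotation_angle_axis(R)
    per_res = _ca_table(open_s, closed_aligned, part)
    if axis is None:
        return HingeMotion(theta, None, None, 0.0, null_axis=True,
                           per_residue_ca_displacement=per_res)
    d_parallel = float(np.dot(t, axis))
    # point on axis: solve (I - R) p = t_perp (perpendicular part of t)
    t_perp = t - d_parallel * axis
    point, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    return HingeMotion(theta, axis, point, d_parallel,
                       per_residue_ca_displacement=per_res)


def _ca_table(a: Structure, b_aligned: Structure, part: DomainPartition) -> dict[int, float]:
    sel = part.selection("moving_domain")
    out = {}
    for xa, xb in zip(sel.apply(a), sel.apply(b_aligned)):
        out[xa.residue_number] = float(np.linalg.norm(xa.coords - xb.coords))
    return out


def ca_displacement_stats(a: Structure, b: Structure,
                          target_range: tuple[int, int],
                          fit_sel: AtomSelection | str,
                          chain_id: str | None = None):
    """Per-residue Cα distances for a target segment after a fit.

    Superposes *b* onto *a* on ``fit_sel`` (typically fixed-domain Cα atoms),
    then reports the Cα distance for each residue in ``target_range`` plus
    mean ± sample standard deviation (n−1).
    """
    if isinstance(fit_sel, str):
        fit_sel = AtomSelection.parse(fit_sel)
    tr, _ = kabsch(np.array([x.coords for x in fit_sel.apply(b)]),
                   np.array([x.coords for x in fit_sel.apply(a)]))
    b_aligned = tr.apply_to_structure(b)
    lo, hi = target_range
    per_residue: dict[int, float] = {}
    for num in range(lo, hi + 1):
        ca_a = _find_ca(a, num, chain_id)
        ca_b = _find_ca(b_aligned, num, chain_id)
        per_residue[num] = float(np.linalg.norm(ca_a - ca_b))
    vals = np.array(list(per_residue.values()))
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return mean, sd, per_residue


def _find_ca(s: Structure, number: int, chain_id: str | None) -> np.ndarray:
    for cid, res in s.iter_residues():
        if res.number == number and (chain_id is None or cid == chain_id):
            if not res.has_atom("CA"):
                raise ValueError(f"residue {number} has no CA atom")
            return res.atom("CA").coords
    raise ValueError(f"residue {number} not found")
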
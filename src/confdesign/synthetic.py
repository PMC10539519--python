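"""Deterministic synthetic-data generators.

Everything the analysis modules consume can be generated here without
downloads: toy two-domain structures with a known screw motion, toy design
energy matrices with a known global minimum, variable-temperature Keq series
and two-Lorentzian spectra from known two-state thermodynamics, and rate
data from known kinetic parameters.  Every generator is bit-deterministic
under a fixed seed (numpy default_rng streams derived from the given seed).

Fixture structures use ideal-ized backbone geometry — no claim of
Ramachandran realism is made.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .energy import Choice, EnergyMatrices
from .hinge import DomainPartition
from .kinetics import RateDataset, michaelis_menten, substrate_inhibition
from .solvers import RotamerAssignment, brute_force_gmec
from .structure import AtomRecord, Chain, Residue, RigidTransform, Structure
from .thermo import Spectrum1D, ln_keq_vant_hoff

__all__ = [
    "ToyDesignProblem",
    "make_toy_structure",
    "make_toy_hinge_pair",
    "make_toy_design_problem",
    "make_vant_hoff_series",
    "make_two_state_spectra",
    "make_kinetics_series",
    "make_absorbance_trace",
]


# ---------------------------------------------------------------------------
# Structures


def _backbone_residue(i: int, ca: np.ndarray, name: str = "ALA",
                      chain_id: str = "A", with_cb: bool = True) -> Residue:
    offs = {
        "N": np.array([-1.20, 0.45, 0.15]),
        "CA": np.zeros(3),
        "C": np.array([1.21, 0.48, -0.12]),
        "O": np.array([1.63, 1.55, -0.45]),
    }
    atoms = []
    for j, (an, off) in enumerate(offs.items()):
        elem = an[0]
        atoms.append(AtomRecord(serial=0, name=an, element=elem, residue_name=name,
                                chain_id=chain_id, residue_number=i,
                                coords=ca + off))
    if with_cb and name != "GLY":
        atoms.append(AtomRecord(serial=0, name="CB", element="C", residue_name=name,
                                chain_id=chain_id, residue_number=i,
                                coords=ca + np.array([-0.52, -1.20, 0.77])))
    return Residue(name=name, number=i, atoms=atoms)


def make_toy_structure(n_res: int = 10, chain_id: str = "A",
                       struct_id: str = "toy") -> Structure:
    """Polyalanine chain on a helical curve (ideal-ized geometry)."""
    residues = []
    for i in range(1, n_res + 1):
        ca = np.array([3.6 * i, 1.8 * math.sin(0.6 * i), 1.8 * math.cos(0.6 * i)])
        residues.append(_backbone_residue(i, ca, chain_id=chain_id))
    return Structure(id=struct_id, chains=[Chain(id=chain_id, residues=residues)])


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = math.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)


def make_toy_hinge_pair(angle_deg: float, axis=(0.0, 0.0, 1.0), n_res: int = 14,
                        axis_point=(0.0, 0.0, 0.0), axis_translation: float = 0.0):
    """Two-domain scaffold whose closed form is the open form with the moving
    domain displaced by exactly the requested screw motion.

    Returns (open_structure, closed_structure, partition).  The fixed domain
    is the first half, the moving domain the second half, with two hinge
    residues in between.
    """
    if not 0.0 < angle_deg < 180.0:
        raise ValueError("angle must be in (0, 180) degrees")
    open_s = make_toy_structure(n_res, struct_id="toy_open")
    closed_s = open_s.copy()
    closed_s.id = "toy_closed"

    half = n_res // 2
    fixed = set(range(1, half))
    hinge = {half, half + 1}
    moving = set(range(half + 2, n_res + 1))
    part = DomainPartition(fixed, moving, hinge, chain_id="A")

    R = _rotation_about_axis(axis, angle_deg)
    p = np.asarray(axis_point, dtype=float)
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    t = p - R @ p + axis_translation * u
    screw = RigidTransform(R, t)
    for _, res in closed_s.iter_residues():
        if res.number in moving:
            for a in res.atoms:
                a.coords = screw.apply(a.coords)
    return open_s, closed_s, part


# ---------------------------------------------------------------------------
# Design problems


@dataclass
class ToyDesignProblem:
    """Random singles/pairs matrices with the exact GMEC stored by enumeration."""

    matrices: EnergyMatrices
    gmec: RotamerAssignment
    seed: int


def make_toy_design_problem(n_pos: int = 3, n_choices: int = 4,
                            seed: int = 0, n_aa: int = 2) -> ToyDesignProblem:
    """Random symmetric design problem; GMEC computed by exhaustive search.

    Choices at each position cycle through ``n_aa`` synthetic amino-acid
    labels so sequence-constrained optimization is exercisable.
    """
    rng = np.random.default_rng(seed)
    aas = [chr(ord("A") + k) for k in range(n_aa)]
    positions = [("A", i + 1) for i in range(n_pos)]
    choices = [[Choice(aas[r % n_aa], r) for r in range(n_choices)]
               for _ in range(n_pos)]
    singles = [rng.normal(0.0, 2.0, size=n_choices) for _ in range(n_pos)]
    pairs = {}
    for i in range(n_pos):
        for j in range(i + 1, n_pos):
            pairs[(i, j)] = rng.normal(0.0, 1.0, size=(n_choices, n_choices))
    m = EnergyMatrices(positions, choices, singles, pairs)
    return ToyDesignProblem(m, brute_force_gmec(m), seed)


# ---------------------------------------------------------------------------
# Two-state thermodynamics series


def make_vant_hoff_series(dh_ref: float, ds_ref: float, dcp: float = 0.0,
                          temperatures=None, t_ref: float = 298.0,
                          noise_sd: float = 0.0, seed: int = 0,
                          multiplicative: bool = True):
    """(T, Keq) observations from the van't Hoff model, optionally noisy.

    Default temperatures are 278–308 K in 5 K steps.  Noise is Gaussian on
    ln Keq (multiplicative on Keq) with standard deviation ``noise_sd``.
    """
    if temperatures is None:
        temperatures = np.arange(278.0, 308.0 + 1e-9, 5.0)
    t = np.asarray(temperatures, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperatures must be > 0 K")
    lnk = ln_keq_vant_hoff(t, dh_ref, ds_ref, dcp, t_ref)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eps = rng.normal(0.0, noise_sd, size=t.shape)
        lnk = lnk + eps if multiplicative else np.log(np.exp(lnk) + eps)
    return list(zip(t.tolist(), np.exp(lnk).tolist()))


def make_two_state_spectra(dh_ref: float, ds_ref: float, dcp: float = 0.0,
                           temperatures=None, t_ref: float = 298.0,
                           center_closed: float = -61.6, center_open: float = -60.4,
                           hwhm_closed: float = 0.08, hwhm_open: float = 0.12,
                           n_points: int = 600, noise_sd: float = 0.0,
                           seed: int = 0) -> list[Spectrum1D]:
    """Two-Lorentzian spectra whose peak areas realize the model populations.

    The closed-state peak is the upfield (lower-ppm) one.  ``noise_sd`` is
    the Gaussian intensity noise relative to the taller peak height.
    """
    series = make_vant_hoff_series(dh_ref, ds_ref, dcp, temperatures, t_ref)
    lo = min(center_closed, center_open) - 1.0
    hi = max(center_closed, center_open) + 1.0
    x = np.linspace(lo, hi, n_points)
    rng = np.random.default_rng(seed)
    spectra = []
    for temp, keq in series:
        p_closed = keq / (1.0 + keq)
        p_open = 1.0 - p_closed
        amp_c = p_closed / (math.pi * hwhm_closed)
        amp_o = p_open / (math.pi * hwhm_open)
        y = (amp_c / (1.0 + ((x - center_closed) / hwhm_closed) ** 2)
             + amp_o / (1.0 + ((x - center_open) / hwhm_open) ** 2))
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd * max(amp_c, amp_o), size=y.shape)
        spectra.append(Spectrum1D(x.copy(), y, temp))
    return spectra


# ---------------------------------------------------------------------------
# Kinetics series


def make_kinetics_series(vmax: float, km: float, ki: float | None = None,
                         concentrations=None, enzyme_conc: float = 1.0,
                         noise_sd: float = 0.0, seed: int = 0,
                         substrate: str = "") -> RateDataset:
    """Rate data from the Michaelis-Menten or substrate-inhibition model.

    Default concentrations span 0.002–40 mM on a log grid (the assay's
    donor-substrate range).  Noise is multiplicative Gaussian with relative
    standard deviation ``noise_sd``.
    """
    if vmax <= 0 or km <= 0 or (ki is not None and ki <= 0):
        raise ValueError("kinetic parameters must be positive")
    if concentrations is None:
        concentrations = np.geomspace(0.002, 40.0, 16)
    s = np.asarray(concentrations, dtype=float)
    v = (substrate_inhibition(s, vmax, km, ki) if ki is not None
         else michaelis_menten(s, vmax, km))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + rng.normal(0.0, noise_sd, size=v.shape))
    return RateDataset(s, v, enzyme_conc=enzyme_conc, substrate=substrate)


def make_absorbance_trace(rate_M_per_s: float, epsilon: float = 6220.0,
                          path_cm: float = 1.0, duration_s: float = 300.0,
                          dt_s: float = 12.0, curvature_onset_s: float | None = None,
                          curvature_tau_s: float = 30.0,
                          noise_sd: float = 0.0, seed: int = 0):
    """A340 trace with a linear phase and optional late saturation curvature.

    After ``curvature_onset_s`` the signal saturates exponentially with time
    constant ``curvature_tau_s`` (substrate depletion)."""
    t = np.arange(0.0, duration_s + 1e-9, dt_s)
    slope = rate_M_per_s * epsilon * path_cm
    a = slope * t
    if curvature_onset_s is not None:
        tau = max(curvature_tau_s, 1e-9)
        late = t > curvature_onset_s
        a_on = slope * curvature_onset_s
        a[late] = a_on + slope * tau * (1.0 - np.exp(-(t[late] - curvature_onset_s) / tau))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd, size=a.shape)
    return t, a
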
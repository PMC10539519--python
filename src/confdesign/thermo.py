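"""Two-state conformational-exchange thermodynamics from 1-D spectra.

A variable-temperature series of one-dimensional spectra (e.g. ¹⁹F traces of
a reporter probe) showing slow two-state exchange is deconvoluted into two
Lorentzian peaks; peak areas give the state populations, their ratio the
equilibrium constant Keq(T), and the temperature series is fit to the linear
or nonlinear (ΔCp ≠ 0) van't Hoff model

    ln Keq = −ΔH°ref/R·(1/T) + ΔS°ref/R − ΔCp/R·[(T−Tref)/T + ln(Tref/T)]

with Tref = 298 K, yielding ΔH°ref, ΔS°ref and ΔCp in the direction of
closing (G_closed − G_open).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import curve_fit

R_GAS = 1.9872e-3    # kcal/(mol·K)
T_REF_DEFAULT = 298.0

__all__ = [
    "Spectrum1D",
    "LorentzianPeak",
    "TwoStateThermo",
    "deconvolute_two_lorentzians",
    "populations_from_peaks",
    "ln_keq_vant_hoff",
    "fit_vant_hoff",
    "gibbs_at_temperature",
]


@dataclass
class Spectrum1D:
    """A 1-D spectrum: chemical-shift axis (ppm), intensities, temperature (K)."""

    axis: np.ndarray
    intensity: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        d = np.diff(self.axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("spectrum axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")


@dataclass
class LorentzianPeak:
    """center (ppm), half-width at half-maximum (ppm), amplitude (height)."""

    center: float
    hwhm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.hwhm <= 0:
            raise ValueError("hwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be ≥ 0")

    @property
    def area(self) -> float:
        return math.pi * self.amplitude * self.hwhm

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return self.amplitude / (1.0 + ((np.asarray(x) - self.center) / self.hwhm) ** 2)


@dataclass
class TwoStateThermo:
    """van't Hoff parameters at Tref, in the direction of closing."""

    dh_ref: float                 # kcal/mol
    ds_ref: float                 # kcal/(mol·K)
    dcp: float = 0.0              # kcal/(mol·K)
    t_ref: float = T_REF_DEFAULT  # K
    uncertainties: dict[str, float] = field(default_factory=dict)
    observations: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.t_ref <= 0:
            raise ValueError("t_ref must be > 0 K")
        for t, k in self.observations:
            if t <= 0 or k <= 0:
                raise ValueError("observations need T > 0 and Keq > 0")

    def ln_keq(self, temperature) -> np.ndarray:
        return ln_keq_vant_hoff(temperature, self.dh_ref, self.ds_ref,
                                self.dcp, self.t_ref)

    def keq(self, temperature) -> np.ndarray:
        return np.exp(self.ln_keq(temperature))


# ---------------------------------------------------------------------------
# Deconvolution


def deconvolute_two_lorentzians(s: Spectrum1D, init: str = "auto"):
    """Fit two Lorentzians + constant baseline to a spectrum.

    Nonlinear least squares via lmfit with positivity bounds on widths and
    amplitudes.  Returns (peakA, peakB, baseline, residual_norm) with peaks
    ordered by center descending (downfield first).  ``init``: "auto" seeds
    centers at the two highest well-separated local maxima, "split" at the
    one-third/two-thirds axis points.
    """
    x, y = s.axis, s.intensity
    if len(x) < 20:
        raise ValueError("need ≥20 axis points for a two-peak deconvolution")
    span = float(x.max() - x.min())
    if init == "auto":
        c1, c2 = _guess_centers(x, y)
    elif init == "split":
        c1, c2 = x.min() + span / 3.0, x.min() + 2.0 * span / 3.0
    else:
        raise ValueError(f"unknown init policy {init!r}")

    model = (lmfit.models.LorentzianModel(prefix="p1_")
             + lmfit.models.LorentzianModel(prefix="p2_")
             + lmfit.models.ConstantModel(prefix="bl_"))
    base = float(np.percentile(y, 5))
    amp0 = max(float(y.max() - base), 1e-12)
    sigma0 = max(span / 50.0, 1e-6)
    params = model.make_params()
    for pfx, c in (("p1_", c1), ("p2_", c2)):
        params[f"{pfx}center"].set(value=c, min=x.min() - span, max=x.max() + span)
        params[f"{pfx}sigma"].set(value=sigma0, min=1e-9)
        params[f"{pfx}amplitude"].set(value=amp0 * sigma0 * math.pi, min=0.0)
    params["bl_c"].set(value=base)
    result = model.fit(y, params, x=x)
    if not result.success:
        raise RuntimeError(f"deconvolution failed: {result.message}")

    peaks = []
    for pfx in ("p1_", "p2_"):
        sigma = float(result.params[f"{pfx}sigma"].value)
        area = float(result.params[f"{pfx}amplitude"].value)  # lmfit amplitude = area
        height = area / (math.pi * sigma)
        peaks.append(LorentzianPeak(float(result.params[f"{pfx}center"].value),
                                    sigma, max(height, 0.0)))
    peaks.sort(key=lambda p: -p.center)
    baseline = float(result.params["bl_c"].value)
    residual_norm = float(np.linalg.norm(result.residual))
    if min(p.area for p in peaks) < 1e-6 * max(p.area for p in peaks):
        warnings.warn("degenerate deconvolution: one peak carries ~no area")
    return peaks[0], peaks[1], baseline, residual_norm


def _guess_centers(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    from scipy.signal import find_peaks

    span = x.max() - x.min()
    baseline = float(np.percentile(y, 5))
    idx, props = find_peaks(y, prominence=1e-4 * (y.max() - baseline))
    if len(idx) >= 2:
        top2 = idx[np.argsort(props["prominences"])[::-1][:2]]
        return float(x[top2[0]]), float(x[top2[1]])
    first = float(x[np.argmax(y)])
    # single visible maximum: seed the second peak off to the emptier side
    return first, first + (span / 4.0 if first < x.mean() else -span / 4.0)


def populations_from_peaks(peak_a: LorentzianPeak, peak_b: LorentzianPeak,
                           closed: str = "upfield"):
    """Fractional populations from peak areas and Keq = p_closed/p_open.

    The closed-state peak is identified by configuration: ``"upfield"``
    (default; the lower-ppm peak) or ``"downfield"``.
    """
    total = peak_a.area + peak_b.area
    if total <= 0:
        raise ValueError("zero total area")
    p_a, p_b = peak_a.area / total, peak_b.area / total
    if closed not in ("upfield", "downfield"):
        raise ValueError(f"unknown closed-peak policy {closed!r}")
    a_is_upfield = peak_a.center < peak_b.center
    a_is_closed = a_is_upfield == (closed == "upfield")
    p_closed, p_open = (p_a, p_b) if a_is_closed else (p_b, p_a)
    if p_open == 0:
        raise ValueError("open-state population is zero; Keq undefined")
    return p_a, p_b, p_closed / p_open


# ---------------------------------------------------------------------------
# van't Hoff


def ln_keq_vant_hoff(temperature, dh_ref: float, ds_ref: float,
                     dcp: float = 0.0, t_ref: float = T_REF_DEFAULT):
    """ln Keq(T) of the (non)linear van't Hoff model at reference Tref."""
    t = np.asarray(temperature, dtype=float)
    return (-dh_ref / R_GAS / t + ds_ref / R_GAS
            - dcp / R_GAS * ((t - t_ref) / t + np.log(t_ref / t)))


def fit_vant_hoff(observations, t_ref: float = T_REF_DEFAULT,
                  model: str = "nonlinear") -> TwoStateThermo:
    """Least-squares fit of ln Keq(T) observations.

    ``observations``: iterable of (T [K], Keq) pairs.  The linear model sets
    ΔCp = 0 and needs ≥3 temperatures; the nonlinear model fits ΔCp too and
    needs ≥4.  Fitting is done in ln Keq space, unweighted; uncertainties are
    1σ from the fit covariance.
    """
    obs = [(float(t), float(k)) for t, k in observations]
    if any(t <= 0 or k <= 0 for t, k in obs):
        raise ValueError("observations need T > 0 and Keq > 0")
    t = np.array([o[0] for o in obs])
    lnk = np.log([o[1] for o in obs])
    if model == "linear":
        if len(obs) < 3:
            raise ValueError("linear fit needs ≥3 temperatures")
        fun = lambda tt, dh, ds: ln_keq_vant_hoff(tt, dh, ds, 0.0, t_ref)
        p0 = (-1.0, 0.0)
        names = ("dh_ref", "ds_ref")
    elif model == "nonlinear":
        if len(obs) < 4:
            raise ValueError("nonlinear fit needs ≥4 temperatures")
        fun = lambda tt, dh, ds, dcp: ln_keq_vant_hoff(tt, dh, ds, dcp, t_ref)
        p0 = (-1.0, 0.0, 0.0)
        names = ("dh_ref", "ds_ref", "dcp")
    else:
        raise ValueError(f"unknown model {model!r}")
    if len(np.unique(t)) < len(p0):
        raise ValueError("singular design: too few distinct temperatures")
    popt, pcov = curve_fit(fun, t, lnk, p0=p0, maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    unc = dict(zip(names, (float(e) for e in perr)))
    dh, ds = float(popt[0]), float(popt[1])
    dcp = float(popt[2]) if model == "nonlinear" else 0.0
    return TwoStateThermo(dh, ds, dcp, t_ref, uncertainties=unc, observations=obs)


def gibbs_at_temperature(t: TwoStateThermo, temperature: float) -> float:
    """ΔG(T) = ΔHref + ΔCp(T−Tref) − T[ΔSref + ΔCp·ln(T/Tref)], kcal/mol.

    Algebraically identical to −RT·ln Keq with Keq from the van't Hoff model.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    tt = float(temperature)
    return (t.dh_ref + t.dcp * (tt - t.t_ref)
            - tt * (t.ds_ref + t.dcp * math.log(tt / t.t_ref)))


def celsius_to_kelvin(celsius: float) -> float:
    return celsius + 273.15
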
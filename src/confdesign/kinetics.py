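"""Steady-state enzyme kinetics: initial rates, Michaelis-Menten and
substrate-inhibition fits, linear-regime efficiency and selectivity.

Rates come from the linear phase of product-appearance absorbance traces
(NADH at 340 nm, ε = 6220 M⁻¹cm⁻¹ by default).  Rate-vs-concentration data
are fit by nonlinear least squares to

    v0 = vmax·[S] / (KM + [S])                      (Michaelis-Menten)
    v0 = vmax·[S] / (KM + [S] + [S]²/Ki)            (substrate inhibition)

with kcat = vmax/[E0].  Catalytic efficiency kcat/KM is also available from
the slope of the linear regime ([S] ≪ KM), and substrate selectivity is the
ratio of efficiencies for two donor substrates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

NADH_EPSILON = 6220.0  # M^-1 cm^-1 at 340 nm

__all__ = [
    "RateDataset",
    "KineticParameters",
    "initial_rate",
    "fit_michaelis_menten",
    "fit_substrate_inhibition",
    "efficiency_linear_regime",
    "selectivity_metrics",
    "michaelis_menten",
    "substrate_inhibition",
]


def michaelis_menten(s, vmax, km):
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def substrate_inhibition(s, vmax, km, ki):
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s + s ** 2 / ki)


@dataclass
class RateDataset:
    """Initial rates vs substrate concentration for one enzyme/substrate."""

    substrate_conc: np.ndarray        # mM
    v0: np.ndarray                    # s^-1 if normalized by [E0], else M/s
    enzyme_conc: float = 1.0          # M (1.0 when v0 already normalized)
    substrate: str = ""
    co_substrate: str = ""
    co_substrate_conc: float = float("nan")

    def __post_init__(self) -> None:
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.v0 = np.asarray(self.v0, dtype=float)
        if self.substrate_conc.shape != self.v0.shape:
            raise ValueError("substrate_conc and v0 must have equal length")
        if np.any(self.substrate_conc < 0):
            raise ValueError("concentrations must be ≥ 0")
        if not np.all(np.isfinite(self.v0)):
            raise ValueError("v0 must be finite")


@dataclass
class KineticParameters:
    kcat: float                       # s^-1
    km: float                         # mM
    kcat_over_km: float               # M^-1 s^-1
    ki: float | None = None           # mM
    uncertainties: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("kcat", "km", "kcat_over_km"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if self.ki is not None and self.ki <= 0:
            raise ValueError("ki must be positive when present")


def initial_rate(time_s, absorbance, epsilon: float = NADH_EPSILON,
                 path_cm: float = 1.0, r2_threshold: float = 0.995,
                 min_points: int = 5) -> float:
    """Initial rate (M/s) from the linear phase of an absorbance trace.

    The linear phase is detected by expanding a prefix window from the start
    of the trace: growth stops at the first point that deviates from the
    current linear fit by more than 4× its RMSE (curvature onset).  The
    detected phase must satisfy R² ≥ ``r2_threshold``; its slope divided by
    ε·path gives the rate.  A flat trace is perfectly linear with slope 0.
    """
    t = np.asarray(time_s, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if len(t) < min_points:
        raise ValueError(f"need ≥{min_points} points, got {len(t)}")
    n = min_points
    while n < len(t):
        slope, intercept, r2, rmse = _linfit(t[:n], a[:n])
        resid = abs(a[n] - (slope * t[n] + intercept))
        if resid > max(4.0 * rmse, 1e-9):
            break
        n += 1
    slope, _, r2, _ = _linfit(t[:n], a[:n])
    if r2 < r2_threshold:
        raise ValueError(f"no linear phase found: best prefix of {n} points has "
                         f"R² = {r2:.4f} < {r2_threshold}")
    return slope / (epsilon * path_cm)


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """slope, intercept, R², residual RMSE of a least-squares line."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    syy = ((y - ym) ** 2).sum()
    if syy < 1e-30:          # flat trace: exactly linear, slope ~0
        return 0.0, float(ym), 1.0, 0.0
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    ss_res = max(syy - slope * sxy, 0.0)
    return (float(slope), float(ym - slope * xm),
            float(1.0 - ss_res / syy), float(math.sqrt(ss_res / n)))


def _propagate_efficiency(kcat, km_mM, kcat_err, km_err):
    km_M = km_mM * 1e-3
    eff = kcat / km_M
    rel = math.sqrt((kcat_err / kcat) ** 2 + (km_err / km_mM) ** 2)
    return eff, eff * rel


def fit_michaelis_menten(d: RateDataset) -> KineticParameters:
    """Nonlinear least-squares Michaelis-Menten fit.

    Warns when the data do not span concentrations below and above the
    fitted KM (poorly constrained saturation); kcat = vmax/[E0] and kcat/KM
    carries first-order propagated uncertainty.
    """
    s, v = d.substrate_conc, d.v0
    if len(s) < 4:
        warnings.warn("fewer than 4 concentrations: Michaelis-Menten fit may be ill-posed")
    vmax0 = float(v.max()) or 1.0
    km0 = float(np.interp(vmax0 / 2.0, np.sort(v), np.sort(s))) or float(np.median(s))
    popt, pcov = curve_fit(michaelis_menten, s, v, p0=(vmax0, max(km0, 1e-6)),
                           bounds=([0, 0], [np.inf, np.inf]), maxfev=20000)
    vmax, km = (float(x) for x in popt)
    perr = np.sqrt(np.diag(pcov))
    if not (s.min() < km < s.max()):
        warnings.warn("fitted KM outside the sampled concentration range; "
                      "consider the linear-regime efficiency estimator")
    kcat = vmax / d.enzyme_conc
    kcat_err = float(perr[0]) / d.enzyme_conc
    eff, eff_err = _propagate_efficiency(kcat, km, kcat_err, float(perr[1]))
    return KineticParameters(kcat, km, eff, None,
                             {"kcat": kcat_err, "km": float(perr[1]),
                              "kcat_over_km": eff_err})


def fit_substrate_inhibition(d: RateDataset) -> KineticParameters:
    """Fit v0 = vmax[S]/(KM + [S] + [S]²/Ki) by nonlinear least squares.

    Warns when no post-peak rate decline is visible (Ki then unconstrained;
    plain Michaelis-Menten is recommended).  The fitted curve peaks at
    [S] = sqrt(KM·Ki).
    """
    s, v = d.substrate_conc, d.v0
    if len(s) < 5:
        raise ValueError("substrate-inhibition fit needs ≥5 concentrations")
    order = np.argsort(s)
    if np.argmax(v[order]) == len(s) - 1:
        warnings.warn("no rate decline at high [S]; Ki is unconstrained — "
                      "consider the plain Michaelis-Menten model")
    vmax0 = float(v.max()) * 1.5
    km0 = max(float(s[order][np.argmax(v[order])]) / 2.0, 1e-6)
    ki0 = max(float(s.max()), 1.0)
    popt, pcov = curve_fit(substrate_inhibition, s, v, p0=(vmax0, km0, ki0),
                           bounds=([0, 0, 0], [np.inf] * 3), maxfev=40000)
    vmax, km, ki = (float(x) for x in popt)
    perr = np.sqrt(np.diag(pcov))
    kcat = vmax / d.enzyme_conc
    kcat_err = float(perr[0]) / d.enzyme_conc
    eff, eff_err = _propagate_efficiency(kcat, km, kcat_err, float(perr[1]))
    return KineticParameters(kcat, km, eff, ki,
                             {"kcat": kcat_err, "km": float(perr[1]),
                              "ki": float(perr[2]), "kcat_over_km": eff_err})


def efficiency_linear_regime(d: RateDataset, km_estimate: float,
                             max_fraction: float = 0.05) -> float:
    """kcat/KM (M⁻¹s⁻¹) from the linear regime v0 = (kcat/KM)[E0][S].

    Uses points with [S] ≤ ``max_fraction``·KM and fits a slope through the
    origin.
    """
    if d.enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be > 0")
    mask = d.substrate_conc <= max_fraction * km_estimate
    if mask.sum() < 3:
        raise ValueError(f"need ≥3 points with [S] ≤ {max_fraction}·KM, have {int(mask.sum())}")
    s = d.substrate_conc[mask] * 1e-3   # mM → M
    v = d.v0[mask]
    slope = float((v * s).sum() / (s ** 2).sum())
    return slope / d.enzyme_conc


def selectivity_metrics(target: KineticParameters, reference_substrate: KineticParameters,
                        baseline: tuple[KineticParameters, KineticParameters] | None = None):
    """Substrate selectivity and fold-switch vs a baseline enzyme.

    selectivity = (kcat/KM for the target substrate) / (kcat/KM for the
    reference substrate); fold_switch = selectivity / baseline selectivity
    when a baseline (e.g. the wild-type pair) is supplied, else None.
    """
    if target.kcat_over_km <= 0 or reference_substrate.kcat_over_km <= 0:
        raise ValueError("efficiencies must be positive")
    selectivity = target.kcat_over_km / reference_substrate.kcat_over_km
    fold = None
    if baseline is not None:
        base_t, base_r = baseline
        base_sel = base_t.kcat_over_km / base_r.kcat_over_km
        if base_sel <= 0:
            raise ValueError("baseline selectivity must be positive")
        fold = selectivity / base_sel
    return selectivity, fold
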
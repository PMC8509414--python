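"""Two-state thermal denaturation analysis of CD melting curves.

The ellipticity at 222 nm of a protein melting between a native (n) and an
unfolded (u) state, each with a linear temperature baseline, follows

    theta(T) = [ (b_n + k_n T) + (b_u + k_u T) K(T) ] / [ 1 + K(T) ],
    K(T) = exp(-dG(T) / (R T)),

with the Gibbs-Helmholtz stability curve (unfolding free energy, positive
below Tm for a stable protein)

    dG(T) = dH (1 - T/Tm) + dCp (T - Tm - T ln(T/Tm)).

Temperatures are Kelvin internally; the public API takes and reports deg C.
dCp is fixed at zero by default (it is weakly identifiable from a single
melt); fitting it is opt-in.  Melts that do not complete inside the scanned
window (Ca2+-loaded EF-hand sensors typically melt above 96 deg C) are
flagged rather than forced to a midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MeltingCurve",
    "DenaturationFit",
    "R_GAS",
    "unfolding_free_energy",
    "fraction_unfolded",
    "melt_signal",
    "fit_melting",
    "unfolding_percent",
    "spectral_descriptors",
]

R_GAS = 8.314  # J/(mol K)
_T0 = 273.15


@dataclass(frozen=True)
class MeltingCurve:
    """Ellipticity-at-222-nm trace vs temperature for one ion condition.

    temperature_c : strictly increasing, within [0, 110] deg C.
    theta222 : ellipticity in mdeg (negative for helical proteins).
    condition : label, e.g. 'EGTA', 'EGTA+Mg', 'Mg+Ca'.
    """

    temperature_c: np.ndarray
    theta222: np.ndarray
    condition: str = ""

    def __post_init__(self):
        t = np.asarray(self.temperature_c, dtype=float)
        th = np.asarray(self.theta222, dtype=float)
        object.__setattr__(self, "temperature_c", t)
        object.__setattr__(self, "theta222", th)
        if t.shape != th.shape or t.ndim != 1:
            raise ValueError("temperature and theta arrays must be equal-length 1-D")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if t.min() < 0 or t.max() > 110:
            raise ValueError("temperatures must lie in [0, 110] deg C")

    def __len__(self) -> int:
        return len(self.temperature_c)


@dataclass(frozen=True)
class DenaturationFit:
    """Two-state fit: baselines, unfolding thermodynamics, convergence flags.

    Baselines are in Kelvin coordinates: native = b_n + k_n * T[K].
    tm_c is the melting temperature in deg C; ``in_window`` is False when
    the fitted Tm lies above the scanned range (reported as '> window max').
    """

    b_n: float
    k_n: float
    b_u: float
    k_u: float
    dh: float           # J/mol at Tm
    dcp: float          # J/(mol K)
    tm_c: float
    rss: float
    converged: bool
    in_window: bool = True
    window_c: tuple = (np.nan, np.nan)
    message: str = ""

    @property
    def tm_k(self) -> float:
        return self.tm_c + _T0


def unfolding_free_energy(fit_or_params, temperature_k,
                          stability_convention: bool = True):
    """Gibbs free energy of unfolding dG(T), J/mol, at temperature(s) in K.

    dG(Tm) = 0 by construction; with the stability convention (default) and
    dH > 0, dG > 0 below Tm.  ``stability_convention=False`` flips the sign
    (folding free energy).
    """
    if isinstance(fit_or_params, DenaturationFit):
        dh, dcp, tm = fit_or_params.dh, fit_or_params.dcp, fit_or_params.tm_k
    else:
        dh, dcp, tm = fit_or_params
    t = np.asarray(temperature_k, dtype=float)
    if np.any(t <= 0):
        raise ValueError("absolute temperature must be > 0 K")
    dg = dh * (1.0 - t / tm) + dcp * (t - tm - t * np.log(t / tm))
    if not stability_convention:
        dg = -dg
    return float(dg) if np.ndim(temperature_k) == 0 else dg


def fraction_unfolded(fit_or_params, temperature_k):
    """Population of the unfolded state, K/(1+K) with K = exp(-dG/RT)."""
    t = np.asarray(temperature_k, dtype=float)
    dg = unfolding_free_energy(fit_or_params, t)
    # logistic in -dG/RT, computed stably
    z = -dg / (R_GAS * t)
    with np.errstate(over="ignore"):
        out = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)),
                       np.exp(z) / (1.0 + np.exp(z)))
    return float(out) if np.ndim(temperature_k) == 0 else out


def melt_signal(temperature_c, b_n, k_n, b_u, k_u, dh, tm_c, dcp=0.0):
    """Forward two-state melt model: theta(T) in the curve's units."""
    t = np.asarray(temperature_c, dtype=float) + _T0
    fu = fraction_unfolded((dh, dcp, tm_c + _T0), t)
    native = b_n + k_n * t
    unfolded = b_u + k_u * t
    out = native * (1.0 - fu) + unfolded * fu
    return float(out) if np.ndim(temperature_c) == 0 else out


def _baseline_guess(t_k: np.ndarray, th: np.ndarray, frac: float = 0.2):
    """Linear fits to the first/last ``frac`` of points: baseline inits."""
    n = max(int(len(t_k) * frac), 3)
    kn, bn = np.polyfit(t_k[:n], th[:n], 1)
    ku, bu = np.polyfit(t_k[-n:], th[-n:], 1)
    return bn, kn, bu, ku


def fit_melting(curve: MeltingCurve,
                init: dict | None = None,
                fit_dcp: bool = False,
                allow_extrapolation: bool = True) -> DenaturationFit:
    """Fit the two-state sloping-baseline model to a melting trace.

    Minimises squared theta residuals over (b_n, k_n, b_u, k_u, dH, Tm)
    and optionally dCp.  When the fitted Tm lands above the scanned window
    the result is flagged ``in_window=False`` (midpoint not observed); with
    ``allow_extrapolation=False`` such fits are reported unconverged.
    """
    if len(curve) < 20:
        raise ValueError(f"need >= 20 points to fit a melt, got {len(curve)}")
    t_k = curve.temperature_c + _T0
    th = curve.theta222
    span = float(np.ptp(th))
    init = dict(init or {})

    bn0, kn0, bu0, ku0 = _baseline_guess(t_k, th)
    # flat-curve screen: if a straight line explains the trace essentially
    # perfectly there is no transition to fit
    k_lin, b_lin = np.polyfit(t_k, th, 1)
    lin_res = th - (b_lin + k_lin * t_k)
    if span == 0 or np.ptp(lin_res) < 1e-9 * max(abs(th).max(), 1.0):
        return DenaturationFit(b_n=bn0, k_n=kn0, b_u=bu0, k_u=ku0,
                               dh=np.nan, dcp=0.0, tm_c=np.nan, rss=np.nan,
                               converged=False, in_window=False,
                               window_c=(curve.temperature_c[0], curve.temperature_c[-1]),
                               message="no transition: trace is a pure baseline")

    t_lo_c, t_hi_c = float(curve.temperature_c[0]), float(curve.temperature_c[-1])
    # Tm init: steepest-slope temperature of a lightly smoothed trace
    dth = np.gradient(th, t_k)
    tm0_k = float(t_k[np.argmax(np.abs(dth))])
    tm0_k = init.get("tm_c", tm0_k - _T0) + _T0
    dh0 = init.get("dh", 250e3)

    names = ["b_n", "k_n", "b_u", "k_u", "dh", "tm_k"] + (["dcp"] if fit_dcp else [])

    def residuals(theta):
        bn, kn, bu, ku, dh, tm_k = theta[:6]
        dcp = theta[6] if fit_dcp else 0.0
        fu = fraction_unfolded((dh, dcp, tm_k), t_k)
        pred = (bn + kn * t_k) * (1 - fu) + (bu + ku * t_k) * fu
        return pred - th

    big = 10.0 * max(abs(th).max(), 1.0)
    lo = [-big, -10.0, -big, -10.0, 1e3, t_lo_c + _T0 - 5.0]
    hi = [big, 10.0, big, 10.0, 5e6, 200.0 + _T0]
    theta0 = [bn0, kn0, bu0, ku0, dh0, tm0_k]
    if fit_dcp:
        lo.append(-1e5)
        hi.append(1e5)
        theta0.append(init.get("dcp", 0.0))

    best = None
    # a second start at the upper window edge catches incomplete melts
    for tm_try in (tm0_k, t_hi_c + _T0, 0.5 * (tm0_k + t_hi_c + _T0)):
        t0 = list(theta0)
        t0[5] = tm_try
        res = least_squares(residuals, np.clip(t0, lo, hi), bounds=(lo, hi),
                            method="trf")
        if best is None or res.cost < best.cost:
            best = res

    bn, kn, bu, ku, dh, tm_k = best.x[:6]
    dcp = float(best.x[6]) if fit_dcp else 0.0
    tm_c = float(tm_k - _T0)
    rss = float(2 * best.cost)
    in_window = t_lo_c <= tm_c <= t_hi_c
    converged = bool(best.success)
    msg = best.message
    if not in_window:
        msg = f"Tm > {t_hi_c:g} deg C (midpoint outside scanned window); " + msg
        if not allow_extrapolation:
            converged = False
    return DenaturationFit(b_n=float(bn), k_n=float(kn), b_u=float(bu),
                           k_u=float(ku), dh=float(dh), dcp=dcp, tm_c=tm_c,
                           rss=rss, converged=converged, in_window=in_window,
                           window_c=(t_lo_c, t_hi_c), message=msg)


def _theta_at(curve: MeltingCurve, temp_c: float, tol: float = 0.5) -> float:
    i = int(np.argmin(np.abs(curve.temperature_c - temp_c)))
    if abs(curve.temperature_c[i] - temp_c) > tol:
        raise ValueError(f"no sampled point within {tol} deg C of {temp_c} deg C")
    return float(curve.theta222[i])


def unfolding_percent(curve: MeltingCurve, t_low: float = 20.0,
                      t_high: float = 96.0) -> float:
    """Percent signal loss across the scan, |theta(96)-theta(20)|/|theta(20)|*100.

    Reported as a magnitude: melting traces of helical proteins are negative
    in mdeg, and the conventional tabulated percentage is positive.
    Endpoints are nearest sampled points within 0.5 deg C.
    """
    th_lo = _theta_at(curve, t_low)
    th_hi = _theta_at(curve, t_high)
    if th_lo == 0:
        raise ValueError("theta at the low-temperature endpoint is zero")
    return abs(th_hi - th_lo) / abs(th_lo) * 100.0


def spectral_descriptors(wavelength_nm: Sequence[float],
                         theta_mdeg: Sequence[float],
                         reference: Sequence[float] | None = None,
                         tol_nm: float = 1.0) -> dict:
    """Far-UV CD descriptors: theta222/theta208 ratio and ion-induced change.

    ``reference`` is the apo-condition (EGTA) trace sampled on the same
    wavelengths; when given, delta_theta_pct = |theta222_ion - theta222_ref|
    / |theta222_ref| * 100 (magnitude convention).  Values at 208 and 222 nm
    are the nearest sampled wavelengths within ``tol_nm``.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    th = np.asarray(theta_mdeg, dtype=float)
    if wl.shape != th.shape:
        raise ValueError("wavelength and theta arrays must match")

    def pick(target, arr):
        i = int(np.argmin(np.abs(wl - target)))
        if abs(wl[i] - target) > tol_nm:
            raise ValueError(f"no sampled wavelength within {tol_nm} nm of {target} nm")
        return float(arr[i])

    th222 = pick(222.0, th)
    th208 = pick(208.0, th)
    if th208 == 0:
        raise ValueError("degenerate spectrum: theta at 208 nm is zero")
    out = {"theta_ratio": th222 / th208, "delta_theta_pct": None}
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != th.shape:
            raise ValueError("reference trace must be sampled on the same wavelengths")
        ref222 = pick(222.0, ref)
        if ref222 == 0:
            raise ValueError("degenerate reference: theta at 222 nm is zero")
        out["delta_theta_pct"] = abs(th222 - ref222) / abs(ref222) * 100.0
    return out
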
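"""Guanylate-cyclase regulation curve fitting.

Cyclase activity (cGMP synthesis rate, arbitrary-but-consistent units) is
modelled as a four-parameter Hill function of either free Ca2+ (inhibition,
decreasing; midpoint IC50) or activator concentration (activation,
increasing; midpoint EC50):

    inhibition:  A(c) = bottom + (top - bottom) / (1 + (c/IC50)**h)
    activation:  A(c) = bottom + (top - bottom) * c**h / (EC50**h + c**h)

Doses are handled in linear space so a zero dose participates naturally
(the activation form evaluates to ``bottom`` at c = 0).  The dynamic range
of regulation is summarised as X-fold = (GC_max - GC_min)/GC_min, and
condition comparisons use a two-tailed two-sample t-test (Welch by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseSeries",
    "CyclaseFit",
    "hill_inhibition",
    "hill_activation",
    "fit_ca_inhibition",
    "fit_activation",
    "x_fold",
    "compare_conditions",
]


@dataclass(frozen=True)
class DoseResponseSeries:
    """Activity vs dose, with the dose axis declared explicitly.

    axis : 'free_ca' (Ca2+-inhibition assay) or 'activator_conc'
    (activation assay, dose = sensor-protein concentration).
    """

    dose: np.ndarray
    activity: np.ndarray
    axis: str
    replicate: np.ndarray | None = None

    def __post_init__(self):
        if self.axis not in ("free_ca", "activator_conc"):
            raise ValueError(f"unknown axis {self.axis!r}")
        d = np.asarray(self.dose, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "dose", d)
        object.__setattr__(self, "activity", a)
        if d.shape != a.shape or d.ndim != 1:
            raise ValueError("dose and activity must be equal-length 1-D arrays")
        if len(np.unique(d)) < 5:
            raise ValueError("need >= 5 distinct doses")
        if np.any(d < 0) or np.any(a < 0):
            raise ValueError("doses and activities must be >= 0")

    def __len__(self) -> int:
        return len(self.dose)


@dataclass(frozen=True)
class CyclaseFit:
    """Fitted Hill parameters of one regulation curve."""

    half_point: float       # IC50 or EC50, M
    hill: float             # cooperativity h
    a_top: float
    a_bottom: float
    x_fold: float
    se: dict
    rss: float
    converged: bool
    axis: str
    message: str = ""


def hill_inhibition(c, ic50: float, h: float, top: float, bottom: float):
    """Decreasing Hill curve; equals (top+bottom)/2 at c = IC50."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** h)


def hill_activation(c, ec50: float, h: float, top: float, bottom: float):
    """Increasing Hill curve; equals bottom at c = 0, (top+bottom)/2 at EC50."""
    c = np.asarray(c, dtype=float)
    ch = c ** h
    return bottom + (top - bottom) * ch / (ec50 ** h + ch)


def x_fold(gc_max: float, gc_min: float) -> float:
    """Dynamic range of cyclase regulation, (GC_max - GC_min)/GC_min."""
    if gc_min <= 0:
        raise ValueError("X-fold undefined: GC_min must be > 0")
    if gc_max < gc_min:
        raise ValueError("GC_max must be >= GC_min")
    return (gc_max - gc_min) / gc_min


def _fit_hill(series: DoseResponseSeries, increasing: bool,
              init: dict | None, fixed_bottom: float | None) -> CyclaseFit:
    d, a = series.dose, series.activity
    lo_a, hi_a = float(np.min(a)), float(np.max(a))
    span = hi_a - lo_a
    if span <= 0:
        return CyclaseFit(half_point=np.nan, hill=np.nan, a_top=hi_a,
                          a_bottom=lo_a, x_fold=np.nan, se={}, rss=np.nan,
                          converged=False, axis=series.axis,
                          message="flat activity: no response to fit")

    # orientation sanity check: Spearman trend must match the model
    rho = stats.spearmanr(d, a).statistic
    want = 1.0 if increasing else -1.0
    if np.isfinite(rho) and rho * want < 0:
        return CyclaseFit(half_point=np.nan, hill=np.nan, a_top=hi_a,
                          a_bottom=lo_a, x_fold=np.nan, se={}, rss=np.nan,
                          converged=False, axis=series.axis,
                          message="data trend opposes the requested model orientation")

    pos = d[d > 0]
    mid0 = float(np.sqrt(pos.min() * pos.max())) if len(pos) else 1.0
    init = dict(init or {})
    x0 = [init.get("half_point", mid0), init.get("hill", 1.5),
          init.get("a_top", hi_a)]
    if fixed_bottom is None:
        x0.append(init.get("a_bottom", max(lo_a, 1e-12)))

    model = hill_activation if increasing else hill_inhibition

    def unpack(theta):
        bottom = fixed_bottom if fixed_bottom is not None else theta[3]
        return theta[0], theta[1], theta[2], bottom

    def residuals(theta):
        mid, h, top, bottom = unpack(theta)
        return model(d, mid, h, top, bottom) - a

    dmax = float(d.max())
    lo = [pos.min() * 1e-3 if len(pos) else 1e-12, 0.1, lo_a - span]
    hi = [dmax * 1e3, 10.0, hi_a + 2 * span]
    if fixed_bottom is None:
        lo.append(0.0)
        hi.append(hi_a + span)

    best = None
    # coarse multi-start over the midpoint (log-spaced across the dose range)
    for mid_try in np.geomspace(max(lo[0], dmax * 1e-4), dmax, 5):
        theta0 = np.array(x0, dtype=float)
        theta0[0] = mid_try
        res = least_squares(residuals, np.clip(theta0, lo, hi), bounds=(lo, hi),
                            method="trf")
        if best is None or res.cost < best.cost:
            best = res
    res = least_squares(residuals, np.clip(np.array(x0, float), lo, hi),
                        bounds=(lo, hi), method="trf")
    if res.cost < best.cost:
        best = res

    mid, h, top, bottom = unpack(best.x)
    rss = float(2 * best.cost)
    n_par = len(best.x)
    dof = max(len(d) - n_par, 1)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        sev = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        sev = np.full(n_par, np.nan)
    names = ["half_point", "hill", "a_top"] + ([] if fixed_bottom is not None else ["a_bottom"])
    se = dict(zip(names, sev))

    try:
        xf = x_fold(max(top, bottom), min(top, bottom)) if min(top, bottom) > 0 else np.nan
    except ValueError:
        xf = np.nan
    return CyclaseFit(half_point=float(mid), hill=float(h), a_top=float(top),
                      a_bottom=float(bottom), x_fold=float(xf) if xf == xf else np.nan,
                      se=se, rss=rss, converged=bool(best.success),
                      axis=series.axis, message=best.message)


def fit_ca_inhibition(series: DoseResponseSeries,
                      init: dict | None = None,
                      fixed_bottom: float | None = None) -> CyclaseFit:
    """Fit the decreasing Hill model (IC50, h) to a Ca2+-inhibition series."""
    if series.axis != "free_ca":
        raise ValueError("fit_ca_inhibition requires axis == 'free_ca'")
    return _fit_hill(series, increasing=False, init=init, fixed_bottom=fixed_bottom)


def fit_activation(series: DoseResponseSeries,
                   init: dict | None = None,
                   fixed_bottom: float | None = None) -> CyclaseFit:
    """Fit the increasing Hill model (EC50, h) to an activator-dose series."""
    if series.axis != "activator_conc":
        raise ValueError("fit_activation requires axis == 'activator_conc'")
    return _fit_hill(series, increasing=True, init=init, fixed_bottom=fixed_bottom)


def compare_conditions(group_a: Sequence[float], group_b: Sequence[float],
                       equal_var: bool = False):
    """Two-tailed two-sample t-test between replicate activity groups.

    Welch's unequal-variance form by default.  Degenerate input (zero
    variance in both groups with equal means) returns t = 0, p = 1 with a
    ``degenerate`` flag instead of NaN.

    Returns
    -------
    dict with keys t, p, degenerate.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "p": 1.0, "degenerate": True}
        return {"t": np.inf if a.mean() > b.mean() else -np.inf,
                "p": 0.0, "degenerate": True}
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {"t": float(t), "p": float(p), "degenerate": False}
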
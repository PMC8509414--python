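"""SEC apparent-MW estimation and DLS size summaries.

Analytical size-exclusion chromatography reports elution volumes; the
distribution coefficient Dc = (Ve - Vv)/(Vt - Vv) places a species between
the void (Dc = 0) and total (Dc = 1) volumes of the column, and a linear
calibration of log10(MW) vs Dc on standards converts Dc to an apparent
molecular weight.  Dynamic light scattering yields hydrodynamic-diameter
time series, summarised as the mean +/- s.e.m. of the first measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SECColumn",
    "CalibrationCurve",
    "distribution_coefficient",
    "estimate_mw",
    "oligomer_ratio",
    "dls_summary",
    "smooth_mcr",
]


@dataclass(frozen=True)
class SECColumn:
    """Column geometry: total volume and void volume, mL."""

    v_total: float
    v_void: float

    def __post_init__(self):
        if not (self.v_total > self.v_void > 0):
            raise ValueError(
                f"need v_total > v_void > 0, got v_total={self.v_total}, v_void={self.v_void}"
            )


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS calibration of log10(MW / kDa) against Dc from standards.

    slope must be negative: larger species elute earlier (smaller Dc).
    """

    slope: float
    intercept: float
    dc_range: tuple

    @classmethod
    def from_standards(cls, mw_kda: Sequence[float], dc: Sequence[float]):
        mw = np.asarray(mw_kda, dtype=float)
        d = np.asarray(dc, dtype=float)
        if len(mw) != len(d) or len(mw) < 2:
            raise ValueError("need >= 2 (mw, dc) standards")
        if len(np.unique(d)) < 2:
            raise ValueError("standards must have distinct Dc values")
        if np.any(mw <= 0):
            raise ValueError("standard MWs must be > 0")
        slope, intercept = np.polyfit(d, np.log10(mw), 1)
        if slope >= 0:
            raise ValueError(
                "calibration slope must be negative (larger species elute earlier)"
            )
        return cls(slope=float(slope), intercept=float(intercept),
                   dc_range=(float(d.min()), float(d.max())))


def distribution_coefficient(v_elute: float, column: SECColumn) -> float:
    """Dc = (Ve - Vv)/(Vt - Vv); warns (but computes) outside [Vv, Vt]."""
    if not (column.v_void <= v_elute <= column.v_total):
        warnings.warn(
            f"elution volume {v_elute} mL outside [{column.v_void}, {column.v_total}] mL",
            stacklevel=2,
        )
    return (v_elute - column.v_void) / (column.v_total - column.v_void)


def estimate_mw(dc: float, cal: CalibrationCurve) -> float:
    """Apparent MW (kDa) from the calibration, 10**(intercept + slope*Dc)."""
    lo, hi = cal.dc_range
    margin = 0.25 * (hi - lo)
    if dc < lo - margin or dc > hi + margin:
        warnings.warn(
            f"Dc={dc:.3f} extrapolates beyond the standards' range [{lo:.3f}, {hi:.3f}]",
            stacklevel=2,
        )
    return float(10.0 ** (cal.intercept + cal.slope * dc))


def oligomer_ratio(apparent_mw_kda: float, monomer_mw_kda: float) -> float:
    """Apparent-to-monomer MW ratio; ~2 suggests a dimer."""
    if monomer_mw_kda <= 0:
        raise ValueError("monomer MW must be > 0")
    return apparent_mw_kda / monomer_mw_kda


def dls_summary(diameters_nm: Sequence[float], n_first: int = 30) -> dict:
    """Mean +/- s.e.m. (nm) of the first ``n_first`` diameter measurements."""
    d = np.asarray(diameters_nm, dtype=float)
    if n_first < 1:
        raise ValueError("n_first must be >= 1")
    if len(d) < n_first:
        raise ValueError(f"need >= {n_first} measurements, got {len(d)}")
    head = d[:n_first]
    sem = float(head.std(ddof=1) / np.sqrt(n_first)) if n_first > 1 else 0.0
    return {"mean_nm": float(head.mean()), "sem_nm": sem, "n": n_first}


def smooth_mcr(time_s: Sequence[float], mcr_kcps: Sequence[float],
               window: int = 5):
    """Centred moving average of a mean-count-rate time series.

    Descriptive export only (no periodicity estimation); the window is in
    samples and is clipped at the series edges.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(mcr_kcps, dtype=float)
    if t.shape != y.shape:
        raise ValueError("time and MCR arrays must match")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd sample count")
    half = window // 2
    out = np.empty_like(y)
    for i in range(len(y)):
        out[i] = y[max(0, i - half):i + half + 1].mean()
    return t, out
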
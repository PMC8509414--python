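"""Chelator-competition titration analysis.

Estimates the macroscopic Ca2+-binding constants of a sensor protein from
an absorbance titration in which the protein competes with a chromophoric
chelator.  Observed absorbance at each total-Ca2+ point is fitted by
nonlinear least squares against the coupled-equilibrium forward model
(:func:`casensor.equilibria.simulate_absorbance`), in log-constant space.

The apparent dissociation constant aggregates the stepwise constants as
Kd_app = 10**(-mean(logK_i)), i.e. the geometric mean of the stepwise
macroscopic dissociation constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .equilibria import Chelator, MixtureState, SequentialBindingModel, solve_free_ca

__all__ = [
    "TitrationSeries",
    "TitrationFit",
    "normalize_titration",
    "fit_binding_constants",
    "kd_apparent",
    "aggregate_replicate_fits",
]

LOGK_BOUNDS = (2.0, 10.0)  # log10 M^-1; enforces positivity, conditions the fit
N_MULTISTART = 8


@dataclass(frozen=True)
class TitrationSeries:
    """One competition titration: total Ca2+ vs absorbance.

    ca_total, absorbance : parallel arrays (M, AU); ca_total strictly increasing.
    q_total, p_total : chelator and protein totals (M).
    wavelength : monitored wavelength in nm (metadata; 263 for Br2-BAPTA).
    """

    ca_total: np.ndarray
    absorbance: np.ndarray
    q_total: float
    p_total: float
    wavelength: float = 263.0

    def __post_init__(self):
        ca = np.asarray(self.ca_total, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "ca_total", ca)
        object.__setattr__(self, "absorbance", ab)
        if ca.shape != ab.shape or ca.ndim != 1:
            raise ValueError("ca_total and absorbance must be equal-length 1-D arrays")
        if len(ca) < 6:
            raise ValueError(f"need >= 6 titration points, got {len(ca)}")
        if not np.all(np.diff(ca) > 0):
            raise ValueError("ca_total must be strictly increasing")
        if not self.q_total > 0:
            raise ValueError("q_total must be > 0")
        if self.p_total < 0:
            raise ValueError("p_total must be >= 0")

    def __len__(self) -> int:
        return len(self.ca_total)


@dataclass(frozen=True)
class TitrationFit:
    """Result of fitting a competition titration."""

    model: SequentialBindingModel
    logK_se: np.ndarray
    kd_app: float
    a_free: float
    a_bound: float
    ca0: float
    rss: float
    converged: bool
    message: str = ""

    @property
    def logK(self) -> tuple:
        return self.model.logK


def kd_apparent(logK: Sequence[float]) -> float:
    """Apparent dissociation constant 10**(-mean(logK)), in M.

    Equals the geometric mean of the stepwise macroscopic dissociation
    constants; invariant under permutation of the constants.
    """
    logK = np.asarray(logK, dtype=float)
    if logK.size == 0:
        raise ValueError("logK list must be non-empty")
    return float(10.0 ** (-logK.mean()))


def normalize_titration(series: TitrationSeries, n_sites: int,
                        a_min: float | None = None,
                        a_max: float | None = None):
    """Normalized (x, y) coordinates of a competition titration.

    x = ca_total / (q_total + n_sites * p_total) — total Ca2+ per binding
    equivalent; y = (A - A_min)/(A_max - A_min) with the endpoints taken
    from the observed extrema unless supplied.

    Returns
    -------
    (x, y) : pair of arrays.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    a = series.absorbance
    lo = float(np.min(a)) if a_min is None else a_min
    hi = float(np.max(a)) if a_max is None else a_max
    if hi == lo:
        raise ValueError("degenerate signal: A_max == A_min")
    x = series.ca_total / (series.q_total + n_sites * series.p_total)
    y = (a - lo) / (hi - lo)
    return x, y


def _predict(series: TitrationSeries, logK, chelator_kd: float,
             a_free: float, a_bound: float, ca0: float) -> np.ndarray:
    model = SequentialBindingModel(logK)
    chel = Chelator(kd=chelator_kd, a_free=a_free, a_bound=a_bound)
    out = np.empty(len(series))
    for i, ca in enumerate(series.ca_total):
        mix = MixtureState(ca_total=ca + ca0, q_total=series.q_total,
                           p_total=series.p_total)
        x = solve_free_ca(mix, model=model, chelator=chel)
        out[i] = chel.absorbance(x)
    return out


def _init_grid(init: Sequence[float], n_starts: int, rng: np.random.Generator):
    """Multi-start initial points: the supplied guess plus jittered copies."""
    init = np.asarray(init, dtype=float)
    starts = [init]
    for _ in range(n_starts - 1):
        jitter = rng.uniform(-1.0, 1.0, size=init.shape)
        starts.append(np.clip(init + jitter, LOGK_BOUNDS[0] + 0.1, LOGK_BOUNDS[1] - 0.1))
    return starts


def fit_binding_constants(series: TitrationSeries,
                          chelator: Chelator,
                          n_sites: int,
                          init: Sequence[float] | None = None,
                          fit_optics: bool = True,
                          fit_ca0: bool = False,
                          n_starts: int = N_MULTISTART,
                          seed: int = 0) -> TitrationFit:
    """Estimate macroscopic binding constants from a competition titration.

    Least squares of observed absorbance against the coupled-equilibrium
    forward model over logK (bounded in [2, 10]), optionally the optical
    endpoints a_free/a_bound and a residual-Ca2+ offset ca0.  Multi-start
    (jittered logK inits) guards against local minima in the 3-site model;
    the best-RSS solution is reported.  Standard errors come from the
    Gauss-Newton curvature (J^T J)^-1 * s^2 at the optimum.
    """
    if series.p_total == 0:
        raise ValueError(
            "series has p_total == 0: no protein to fit; "
            "use the chelator-only forward model for consistency checks"
        )
    if init is None:
        init = np.linspace(6.0, 4.0, n_sites)
    init = np.asarray(init, dtype=float)
    if len(init) != n_sites:
        raise ValueError(f"init has {len(init)} values but n_sites={n_sites}")

    a_lo, a_hi = float(np.min(series.absorbance)), float(np.max(series.absorbance))
    span = a_hi - a_lo
    n_par = n_sites + (2 if fit_optics else 0) + (1 if fit_ca0 else 0)
    if len(series) <= n_par:
        raise ValueError(f"{len(series)} points cannot constrain {n_par} parameters")

    def unpack(theta):
        logK = theta[:n_sites]
        k = n_sites
        if fit_optics:
            af, ab = theta[k], theta[k + 1]
            k += 2
        else:
            af, ab = chelator.a_free, chelator.a_bound
        ca0 = theta[k] if fit_ca0 else 0.0
        return logK, af, ab, ca0

    def residuals(theta):
        logK, af, ab, ca0 = unpack(theta)
        if af == ab:  # keep the forward model valid inside the optimizer
            ab = af + 1e-12
        pred = _predict(series, logK, chelator.kd, af, ab, ca0)
        return pred - series.absorbance

    lo = [LOGK_BOUNDS[0]] * n_sites
    hi = [LOGK_BOUNDS[1]] * n_sites
    extra = []
    if fit_optics:
        # optics endpoints: allow generous range around the observed extrema
        lo += [a_lo - 2 * span, a_lo - 2 * span]
        hi += [a_hi + 2 * span, a_hi + 2 * span]
        extra += [chelator.a_free, chelator.a_bound]
    if fit_ca0:
        lo += [0.0]
        hi += [5e-6]  # residual Ca2+ after decalcification, M
        extra += [1e-7]

    rng = np.random.default_rng(seed)
    best = None
    for start_logK in _init_grid(init, n_starts, rng):
        theta0 = np.concatenate([start_logK, extra])
        try:
            res = least_squares(residuals, theta0, bounds=(lo, hi), method="trf")
        except RuntimeError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed for the titration fit")

    logK, af, ab, ca0 = unpack(best.x)
    rss = float(2 * best.cost)
    dof = max(len(series) - n_par, 1)
    s2 = rss / dof
    JtJ = best.jac.T @ best.jac
    try:
        cov = s2 * np.linalg.inv(JtJ)
        se = np.sqrt(np.clip(np.diag(cov)[:n_sites], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(n_sites, np.nan)

    converged = bool(best.success)
    # keep the fitted order: the binding polynomial depends on the ordering
    # of the stepwise constants (beta_i are cumulative products), so
    # reordering after the fit would change the model away from the optimum
    return TitrationFit(
        model=SequentialBindingModel(logK),
        logK_se=np.asarray(se),
        kd_app=kd_apparent(logK),
        a_free=float(af),
        a_bound=float(ab),
        ca0=float(ca0),
        rss=rss,
        converged=converged,
        message=best.message,
    )


def aggregate_replicate_fits(fits: Sequence[TitrationFit]):
    """Average logK across technical-replicate fits, as assays report them.

    Returns
    -------
    dict with per-constant mean and standard deviation (ddof=1 when n >= 2)
    and the apparent Kd computed from the averaged constants.
    """
    if not fits:
        raise ValueError("no fits to aggregate")
    n_sites = {f.model.n_sites for f in fits}
    if len(n_sites) != 1:
        raise ValueError("replicate fits disagree on the number of sites")
    mat = np.array([f.logK for f in fits])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if len(fits) >= 2 else np.zeros(mat.shape[1])
    return {
        "logK_mean": mean,
        "logK_sd": sd,
        "kd_app": kd_apparent(mean),
        "n_replicates": len(fits),
    }
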
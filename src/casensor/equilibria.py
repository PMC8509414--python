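"""Coupled Ca2+-binding equilibria for a sequential n-site sensor protein.

The protein is described by macroscopic (Adair) association constants
``K_1 ... K_n`` (stepwise, in M^-1, stored as log10).  The binding
polynomial is

    Z(x) = 1 + beta_1 x + beta_2 x^2 + ... + beta_n x^n,
    beta_i = prod_{j<=i} K_j,

with ``x`` the free Ca2+ concentration, and the mean number of bound ions
per protein is nu(x) = x dlnZ/dx = sum_i i beta_i x^i / Z(x).

A chromophoric chelator (e.g. 5,5'Br2-BAPTA, monitored at 263 nm) binds a
single Ca2+ with dissociation constant ``kd`` and changes absorbance from
``a_free`` to ``a_bound``.  Mixing protein and chelator couples the two
equilibria through the total-Ca2+ mass balance

    ca_total = x + q_total * x/(kd + x) + p_total * nu(x),

which this module inverts numerically to obtain the free concentration and
hence the forward-modelled absorbance of a competition titration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SequentialBindingModel",
    "Chelator",
    "MixtureState",
    "occupancy",
    "solve_free_ca",
    "simulate_absorbance",
]

#: Absolute tolerance on free-Ca2+ concentration (M) for the root search.
CA_SOLVER_XTOL = 1e-12
#: Relative tolerance on the mass balance at the returned root.
CA_SOLVER_RTOL = 1e-10


@dataclass(frozen=True)
class SequentialBindingModel:
    """Macroscopic sequential Ca2+-binding model.

    Parameters
    ----------
    logK : sequence of float
        log10 of the stepwise macroscopic association constants (M^-1),
        ordered K_1 ... K_n.  The number of sites is ``len(logK)``.
    """

    logK: tuple = ()

    def __init__(self, logK: Sequence[float]):
        logK = tuple(float(k) for k in logK)
        if len(logK) < 1:
            raise ValueError("at least one binding site (logK value) is required")
        object.__setattr__(self, "logK", logK)
        beta = np.cumprod(np.power(10.0, np.asarray(logK)))
        if not np.all(np.isfinite(beta)) or not np.all(beta > 0):
            raise ValueError("cumulative binding constants overflow or are non-positive")

    @property
    def n_sites(self) -> int:
        return len(self.logK)

    @property
    def beta(self) -> np.ndarray:
        """Cumulative association constants beta_i = prod_{j<=i} 10**logK_j."""
        return np.cumprod(np.power(10.0, np.asarray(self.logK)))


@dataclass(frozen=True)
class Chelator:
    """One-site chromophoric chelator.

    kd : dissociation constant, M.
    a_free / a_bound : absorbance of the Ca2+-free / Ca2+-bound form (AU).
    For 5,5'Br2-BAPTA at 263 nm, a_free > a_bound (signal drops on binding).
    """

    kd: float
    a_free: float
    a_bound: float

    def __post_init__(self):
        if not self.kd > 0:
            raise ValueError(f"chelator kd must be > 0, got {self.kd}")
        if self.a_free == self.a_bound:
            raise ValueError("a_free == a_bound: chelator signal does not change on binding")

    def fraction_bound(self, free_ca):
        """Fraction of chelator in the Ca2+-bound form at free [Ca2+] ``free_ca``."""
        x = np.asarray(free_ca, dtype=float)
        return x / (self.kd + x)

    def absorbance(self, free_ca):
        fb = self.fraction_bound(free_ca)
        return self.a_free * (1.0 - fb) + self.a_bound * fb


@dataclass(frozen=True)
class MixtureState:
    """Total concentrations (M) of Ca2+, chelator and protein in a cuvette."""

    ca_total: float
    q_total: float = 0.0
    p_total: float = 0.0

    def __post_init__(self):
        for name in ("ca_total", "q_total", "p_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


def occupancy(model: SequentialBindingModel, free_ca) -> float | np.ndarray:
    """Mean number of Ca2+ ions bound per protein at free [Ca2+] ``free_ca``.

    Adair average saturation nu(x) = sum_i i beta_i x^i / (1 + sum_i beta_i x^i).
    Evaluated in a numerically safe way by factoring out the dominant term.
    """
    x = np.asarray(free_ca, dtype=float)
    if np.any(x < 0):
        raise ValueError("free_ca must be >= 0")
    beta = model.beta
    i = np.arange(1, model.n_sites + 1)
    # log-space terms: t_i = log(beta_i) + i*log(x); beta_0 term is 0 at log(1)
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    terms = np.log(beta)[..., :] + np.multiply.outer(logx, i)  # (..., n)
    terms = np.concatenate([np.zeros(terms.shape[:-1] + (1,)), terms], axis=-1)
    m = np.max(terms, axis=-1, keepdims=True)
    w = np.exp(terms - m)
    num = np.sum(w[..., 1:] * i, axis=-1)
    den = np.sum(w, axis=-1)
    out = num / den
    out = np.where(x == 0, 0.0, out)
    return float(out) if np.isscalar(free_ca) or np.ndim(free_ca) == 0 else out


def _mass_balance(x: float, mix: MixtureState,
                  model: SequentialBindingModel | None,
                  chelator: Chelator | None) -> float:
    bound = 0.0
    if chelator is not None and mix.q_total > 0:
        bound += mix.q_total * x / (chelator.kd + x)
    if model is not None and mix.p_total > 0:
        bound += mix.p_total * occupancy(model, x)
    return x + bound - mix.ca_total


def solve_free_ca(mix: MixtureState,
                  model: SequentialBindingModel | None = None,
                  chelator: Chelator | None = None) -> float:
    """Free Ca2+ concentration (M) satisfying the total-Ca2+ mass balance.

    The balance f(x) = x + q*x/(kd+x) + p*nu(x) - ca_total is strictly
    increasing on [0, ca_total], so the root is unique; it is found by
    bracketed root search (Brent).  Raises ``RuntimeError`` with diagnostics
    if the bracket fails (unreachable for valid inputs).
    """
    if mix.ca_total == 0:
        return 0.0
    no_binder = (model is None or mix.p_total == 0) and (chelator is None or mix.q_total == 0)
    if no_binder:
        return mix.ca_total

    f = lambda x: _mass_balance(x, mix, model, chelator)
    lo, hi = 0.0, mix.ca_total
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise RuntimeError(
            "free-Ca solver bracket failed: "
            f"f(0)={flo:.3e}, f(ca_total)={fhi:.3e}, mix={mix}"
        )
    # xtol scales with the concentration so micromolar problems converge to
    # machine precision rather than to a fixed absolute floor
    xtol = max(mix.ca_total * 1e-16, 1e-300)
    x = brentq(f, lo, hi, xtol=xtol, rtol=4 * np.finfo(float).eps, maxiter=200)
    resid = abs(f(x)) / max(mix.ca_total, CA_SOLVER_XTOL)
    if resid > CA_SOLVER_RTOL:
        raise RuntimeError(
            f"free-Ca solver did not reach tolerance: relative residual {resid:.2e}"
        )
    return float(x)


def simulate_absorbance(mix: MixtureState,
                        model: SequentialBindingModel | None,
                        chelator: Chelator) -> float:
    """Forward-modelled absorbance of a protein/chelator competition mixture.

    Solves the coupled mass balance for free Ca2+, then maps the chelator's
    bound fraction onto its optical endpoints:
    A = a_free*(1-f_b) + a_bound*f_b with f_b = x/(kd+x).
    """
    x = solve_free_ca(mix, model=model, chelator=chelator)
    return float(chelator.absorbance(x))
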
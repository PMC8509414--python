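"""Seeded generators for every assay series the analysis modules consume.

Each generator is a pure function of (truth parameters, protocol, seed):
the same call yields byte-identical data.  Defaults reproduce the study
conditions of the characterisation protocol this package implements —
stepwise 3 uM Ca2+ additions into ~25 uM chromophoric chelator for the
competition titration, 12 log-spaced Ca2+ doses spanning 19 nM - 1 mM for
cyclase inhibition, 8 activator doses over 0-10 uM for activation, and
20-96 deg C melts — with configurable Gaussian noise (1% of optical span,
5% proportional, and 2% of trace span respectively).

``PRESETS`` carries the characterised parameter sets of the WT and N104H
GCAP1 variants so that a paper-like pipeline run needs no external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cyclase import DoseResponseSeries, hill_activation, hill_inhibition
from .equilibria import Chelator, MixtureState, SequentialBindingModel, simulate_absorbance
from .thermal import MeltingCurve, melt_signal
from .titration import TitrationSeries

__all__ = [
    "NoiseSpec",
    "gen_titration",
    "gen_dose_response",
    "gen_melting",
    "gen_sec_standards",
    "PRESETS",
    "DEFAULT_CHELATOR",
]

#: 5,5'Br2-BAPTA at 263 nm: Kd is a literature calibration value (the
#: competition protocol does not print one); optical endpoints are in AU
#: for a ~25 uM chelator solution.
DEFAULT_CHELATOR = Chelator(kd=2.3e-6, a_free=0.55, a_bound=0.15)

#: Characterised parameter sets of the two GCAP1 variants: Hill regulation
#: descriptors (IC50/h for Ca2+ inhibition, EC50 for GC activation, X-fold
#: dynamic range), macroscopic Ca2+-binding constants (log10 M^-1), their
#: apparent Kd, and apo-state (EGTA) melting temperatures.
PRESETS = {
    "WT": {
        "ic50_M": 0.26e-6, "hill": 2.05, "ec50_M": 3.2e-6, "x_fold": 7.4,
        "logK": (7.07, 5.55), "kd_app_M": 0.49e-6, "tm_egta_C": 54.1,
    },
    "N104H": {
        "ic50_M": 0.52e-6, "hill": 1.77, "ec50_M": 1.6e-6, "x_fold": 3.9,
        "logK": (5.92, 4.70, 4.23), "kd_app_M": 11.2e-6, "tm_egta_C": 48.1,
    },
}


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise description.

    kind : 'absolute' (sigma in signal units) or 'proportional'
    (sigma as a fraction of each true value).
    """

    kind: str = "absolute"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("absolute", "proportional"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.sigma == 0:
            return np.asarray(values, dtype=float).copy()
        rng = np.random.default_rng(self.seed)
        v = np.asarray(values, dtype=float)
        scale = self.sigma * (np.abs(v) if self.kind == "proportional" else 1.0)
        return v + rng.normal(0.0, 1.0, size=v.shape) * scale


def gen_titration(model: SequentialBindingModel,
                  chelator: Chelator = DEFAULT_CHELATOR,
                  p_total: float = 20e-6,
                  q_total: float = 25e-6,
                  step: float = 3e-6,
                  n_points: int = 30,
                  noise: NoiseSpec = NoiseSpec()) -> TitrationSeries:
    """Synthetic competition titration: stepwise Ca2+ additions.

    ca_total runs 0, step, 2*step, ...; absorbance is the coupled-equilibrium
    forward model plus noise.  Default noise convention: for
    kind='absolute', ``sigma`` is interpreted as a fraction of the
    chelator's optical span (so 0.01 means 1% of span).
    """
    ca = step * np.arange(n_points)
    a_true = np.array([
        simulate_absorbance(MixtureState(c, q_total, p_total), model, chelator)
        for c in ca
    ])
    spec = noise
    if noise.kind == "absolute" and noise.sigma > 0:
        span = abs(chelator.a_free - chelator.a_bound)
        spec = NoiseSpec("absolute", noise.sigma * span, noise.seed)
    a = spec.apply(a_true)
    return TitrationSeries(ca_total=ca, absorbance=a,
                           q_total=q_total, p_total=p_total)


def gen_dose_response(half_point: float,
                      hill: float,
                      a_top: float,
                      a_bottom: float,
                      axis: str = "free_ca",
                      doses: np.ndarray | None = None,
                      noise: NoiseSpec = NoiseSpec(kind="proportional", sigma=0.05)
                      ) -> DoseResponseSeries:
    """Synthetic cyclase regulation series on either dose axis.

    Defaults: 12 log-spaced Ca2+ doses over 19 nM - 1 mM for the
    inhibition axis; 8 linear activator doses over 0 - 10 uM for the
    activation axis (including the zero-dose baseline).
    """
    if doses is None:
        if axis == "free_ca":
            doses = np.geomspace(19e-9, 1e-3, 12)
        else:
            doses = np.linspace(0.0, 10e-6, 8)
    doses = np.asarray(doses, dtype=float)
    model = hill_inhibition if axis == "free_ca" else hill_activation
    a_true = model(doses, half_point, hill, a_top, a_bottom)
    a = np.clip(noise.apply(a_true), 0.0, None)
    return DoseResponseSeries(dose=doses, activity=a, axis=axis)


def gen_melting(tm_c: float,
                dh: float = 300e3,
                dcp: float = 0.0,
                b_n: float = -26.0,
                k_n: float = 0.02,
                b_u: float = -21.0,
                k_u: float = 0.02,
                t_range: tuple = (20.0, 96.0),
                n_points: int = 77,
                noise: NoiseSpec = NoiseSpec()) -> MeltingCurve:
    """Synthetic CD melting trace from the two-state sloping-baseline model.

    Baseline defaults give a helical-protein-like trace (~ -20 mdeg native
    at 20 deg C relaxing to ~ -15 mdeg unfolded at 96 deg C; intercepts are
    in Kelvin coordinates).  For kind='absolute' noise, ``sigma`` is a
    fraction of the trace span (0.02 = 2% of span).
    """
    t = np.linspace(t_range[0], t_range[1], n_points)
    th_true = melt_signal(t, b_n, k_n, b_u, k_u, dh, tm_c, dcp)
    spec = noise
    if noise.kind == "absolute" and noise.sigma > 0:
        span = float(np.ptp(th_true))
        spec = NoiseSpec("absolute", noise.sigma * max(span, 1e-12), noise.seed)
    th = spec.apply(th_true)
    return MeltingCurve(temperature_c=t, theta222=th)


def gen_sec_standards(slope: float, intercept: float,
                      dc_list: np.ndarray,
                      noise: NoiseSpec = NoiseSpec()):
    """Synthetic SEC calibration standards on a log-linear law.

    Returns (mw_kda, dc) arrays with MW = 10**(intercept + slope*dc) and
    noise applied on the log10(MW) scale (absolute, in log units).
    """
    dc = np.asarray(dc_list, dtype=float)
    log_mw = intercept + slope * dc
    log_mw = noise.apply(log_mw)
    return 10.0 ** log_mw, dc
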
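"""CSV readers/writers, configuration, and the end-to-end pipeline.

CSV dialects (decimal point, UTF-8, mandatory header):

===============  =================================
assay            header
===============  =================================
titration        ``ca_total_uM,a263``
dose-response    ``dose_uM,activity,replicate``
melt             ``temp_C,theta222_mdeg``
spectrum         ``wavelength_nm,theta_mdeg``
sec              ``sample,v_elute_mL``
sec standards    ``mw_kDa,v_elute_mL``
dls              ``time_s,diameter_nm,mcr_kcps``
===============  =================================

Assay-level metadata that is not per-row (chelator Kd, totals, dose axis,
column volumes, seeds) lives in a YAML sidecar validated by
:class:`AnalysisConfig`; unknown keys are rejected explicitly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cyclase import DoseResponseSeries, fit_activation, fit_ca_inhibition
from .equilibria import Chelator
from .hydrodynamics import (CalibrationCurve, SECColumn,
                            distribution_coefficient, estimate_mw)
from .synthetic import (DEFAULT_CHELATOR, PRESETS, NoiseSpec, gen_dose_response,
                        gen_melting, gen_titration)
from .equilibria import SequentialBindingModel
from .thermal import MeltingCurve, fit_melting, unfolding_percent
from .titration import TitrationSeries, fit_binding_constants

__all__ = [
    "DIALECTS",
    "AnalysisConfig",
    "read_series",
    "write_series",
    "run_pipeline",
]

log = logging.getLogger("casensor")

DIALECTS = {
    "titration": ["ca_total_uM", "a263"],
    "dose_response": ["dose_uM", "activity", "replicate"],
    "melt": ["temp_C", "theta222_mdeg"],
    "spectrum": ["wavelength_nm", "theta_mdeg"],
    "sec": ["sample", "v_elute_mL"],
    "sec_standards": ["mw_kDa", "v_elute_mL"],
    "dls": ["time_s", "diameter_nm", "mcr_kcps"],
}


class ParseError(ValueError):
    """Malformed input file; message names the offending column or row."""


def _read_csv(path, dialect: str) -> pd.DataFrame:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty") from None
    expected = DIALECTS[dialect]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing column(s) {missing} for dialect {dialect!r}; "
            f"found {list(df.columns)}"
        )
    if len(df) == 0:
        raise ParseError(f"{path}: no data rows")
    numeric = [c for c in expected if c not in ("sample",)]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} at data row {bad[0] + 1}"
            )
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0]) + 1
            raise ParseError(f"{path}: missing value in column {col!r} at data row {row}")
        df[col] = coerced
    return df


def read_series(path, dialect: str, meta: dict | None = None):
    """Read a CSV of the given dialect into the corresponding typed object.

    ``meta`` supplies the sidecar values the object needs (totals for a
    titration, axis for a dose-response...).  SEC-type dialects return the
    validated DataFrame, as they are joined with other inputs downstream.
    """
    df = _read_csv(path, dialect)
    meta = meta or {}
    if dialect == "titration":
        return TitrationSeries(
            ca_total=df["ca_total_uM"].to_numpy() * 1e-6,
            absorbance=df["a263"].to_numpy(),
            q_total=float(meta.get("q_total_uM", 25.0)) * 1e-6,
            p_total=float(meta.get("p_total_uM", 0.0)) * 1e-6,
        )
    if dialect == "dose_response":
        return DoseResponseSeries(
            dose=df["dose_uM"].to_numpy() * 1e-6,
            activity=df["activity"].to_numpy(),
            axis=meta.get("axis", "free_ca"),
            replicate=df["replicate"].to_numpy(),
        )
    if dialect == "melt":
        return MeltingCurve(
            temperature_c=df["temp_C"].to_numpy(),
            theta222=df["theta222_mdeg"].to_numpy(),
            condition=meta.get("condition", ""),
        )
    return df


def write_series(obj, path, dialect: str) -> None:
    """Write a typed series back to its CSV dialect (round-trip safe)."""
    path = Path(path)
    if dialect == "titration":
        df = pd.DataFrame({"ca_total_uM": obj.ca_total * 1e6, "a263": obj.absorbance})
    elif dialect == "dose_response":
        rep = obj.replicate if obj.replicate is not None else np.ones(len(obj), dtype=int)
        df = pd.DataFrame({"dose_uM": obj.dose * 1e6, "activity": obj.activity,
                           "replicate": rep})
    elif dialect == "melt":
        df = pd.DataFrame({"temp_C": obj.temperature_c, "theta222_mdeg": obj.theta222})
    else:
        raise ValueError(f"no writer for dialect {dialect!r}")
    df.to_csv(path, index=False)


_CONFIG_FIELDS = {
    "assay": str,            # titration | ca_inhibition | activation | melt | sec
    "data": str,             # input CSV path (omit when simulating)
    "out_dir": str,
    "variant": str,          # preset name for simulation, label otherwise
    "n_sites": int,
    "q_total_uM": float,
    "p_total_uM": float,
    "chelator_kd_uM": float,
    "fit_optics": bool,
    "fit_ca0": bool,
    "axis": str,
    "condition": str,
    "fit_dcp": bool,
    "v_total_mL": float,
    "v_void_mL": float,
    "standards": str,        # standards CSV path for SEC
    "simulate": bool,
    "noise_sigma": float,
    "seed": int,
}

_CONFIG_DEFAULTS = {
    "assay": "titration",
    "out_dir": "casensor_out",
    "variant": "N104H",
    "n_sites": 3,
    "q_total_uM": 25.0,
    "p_total_uM": 20.0,
    "chelator_kd_uM": 2.3,
    "fit_optics": True,
    "fit_ca0": False,
    "axis": "free_ca",
    "condition": "EGTA",
    "fit_dcp": False,
    "v_total_mL": 25.0,
    "v_void_mL": 8.0,
    "simulate": False,
    "noise_sigma": 0.0,
    "seed": 0,
}


@dataclasses.dataclass
class AnalysisConfig:
    """Validated analysis configuration (see ``_CONFIG_FIELDS`` for keys)."""

    values: dict

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        unknown = set(raw) - set(_CONFIG_FIELDS)
        if unknown:
            raise ValueError(
                f"unknown config key(s): {sorted(unknown)}; "
                f"allowed: {sorted(_CONFIG_FIELDS)}"
            )
        merged = dict(_CONFIG_DEFAULTS)
        merged.update(raw)
        for key, val in merged.items():
            want = _CONFIG_FIELDS[key]
            if want in (int, float) and isinstance(val, (int, float)):
                merged[key] = want(val)
            elif not isinstance(val, want):
                raise ValueError(f"config key {key!r} must be {want.__name__}, got {val!r}")
        return cls(values=merged)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def __getitem__(self, key):
        return self.values[key]


def _fit_report_rows(cfg: AnalysisConfig, result) -> list[dict]:
    """Flatten a fit object into Table-style report rows with units."""
    v = cfg["variant"]
    rows = []
    if hasattr(result, "kd_app"):  # titration
        for i, (k, se) in enumerate(zip(result.logK, result.logK_se), start=1):
            rows.append({"variant": v, "quantity": f"logK_{i}", "value": k,
                         "se": se, "units": "log10 M^-1"})
        rows.append({"variant": v, "quantity": "Kd_app", "value": result.kd_app * 1e6,
                     "se": np.nan, "units": "uM"})
    elif hasattr(result, "half_point"):  # cyclase
        name = "IC50" if result.axis == "free_ca" else "EC50"
        rows.append({"variant": v, "quantity": name, "value": result.half_point * 1e6,
                     "se": result.se.get("half_point", np.nan) * 1e6
                     if np.isfinite(result.se.get("half_point", np.nan)) else np.nan,
                     "units": "uM"})
        rows.append({"variant": v, "quantity": "h", "value": result.hill,
                     "se": result.se.get("hill", np.nan), "units": ""})
        rows.append({"variant": v, "quantity": "X-fold", "value": result.x_fold,
                     "se": np.nan, "units": ""})
    elif hasattr(result, "tm_c"):  # melt
        tm = result.tm_c if result.in_window else np.nan
        tm_str = f"{result.tm_c:.1f}" if result.in_window else f">{result.window_c[1]:g}"
        rows.append({"variant": v, "quantity": "Tm", "value": tm, "se": np.nan,
                     "units": "deg C", "display": tm_str})
    return rows


def run_pipeline(config: AnalysisConfig, seed: int | None = None) -> dict:
    """Run one configured assay end to end; returns the report bundle.

    When ``simulate`` is set, input data are generated from the named
    variant preset before analysis.  Writes <out_dir>/report.csv,
    report.txt and run_log.json; any stage failure is recorded in the
    bundle with ``ok=False`` (the CLI maps this to a non-zero exit).
    """
    cfg = config
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"] if seed is None else seed
    assay = cfg["assay"]
    preset = PRESETS.get(cfg["variant"], PRESETS["N104H"])
    bundle = {"ok": True, "assay": assay, "rows": [], "log": {
        "package": "casensor", "version": __version__, "seed": seed,
        "config": cfg.values,
    }}
    try:
        if assay == "titration":
            chel = Chelator(kd=cfg["chelator_kd_uM"] * 1e-6,
                            a_free=DEFAULT_CHELATOR.a_free,
                            a_bound=DEFAULT_CHELATOR.a_bound)
            if cfg["simulate"]:
                model = SequentialBindingModel(preset["logK"])
                series = gen_titration(
                    model, chel, p_total=cfg["p_total_uM"] * 1e-6,
                    q_total=cfg["q_total_uM"] * 1e-6,
                    noise=NoiseSpec("absolute", cfg["noise_sigma"], seed))
                write_series(series, out_dir / "titration.csv", "titration")
            else:
                series = read_series(cfg["data"], "titration", cfg.values)
            fit = fit_binding_constants(series, chel, n_sites=cfg["n_sites"],
                                        fit_optics=cfg["fit_optics"],
                                        fit_ca0=cfg["fit_ca0"], seed=seed)
            if not fit.converged:
                bundle["ok"] = False
            bundle["rows"] = _fit_report_rows(cfg, fit)
        elif assay in ("ca_inhibition", "activation"):
            axis = "free_ca" if assay == "ca_inhibition" else "activator_conc"
            if cfg["simulate"]:
                half = preset["ic50_M"] if axis == "free_ca" else preset["ec50_M"]
                h = preset["hill"] if axis == "free_ca" else 2.0
                series = gen_dose_response(
                    half, h, a_top=1.0 + preset["x_fold"], a_bottom=1.0, axis=axis,
                    noise=NoiseSpec("proportional", cfg["noise_sigma"] or 0.05, seed))
                write_series(series, out_dir / f"{assay}.csv", "dose_response")
            else:
                series = read_series(cfg["data"], "dose_response",
                                     {"axis": axis})
            fitter = fit_ca_inhibition if axis == "free_ca" else fit_activation
            fit = fitter(series)
            if not fit.converged:
                bundle["ok"] = False
            bundle["rows"] = _fit_report_rows(cfg, fit)
        elif assay == "melt":
            if cfg["simulate"]:
                curve = gen_melting(preset["tm_egta_C"],
                                    noise=NoiseSpec("absolute",
                                                    cfg["noise_sigma"] or 0.02, seed))
                write_series(curve, out_dir / "melt.csv", "melt")
            else:
                curve = read_series(cfg["data"], "melt", cfg.values)
            fit = fit_melting(curve, fit_dcp=cfg["fit_dcp"])
            if not (fit.converged or not fit.in_window):
                bundle["ok"] = False
            bundle["rows"] = _fit_report_rows(cfg, fit)
            try:
                bundle["rows"].append({
                    "variant": cfg["variant"], "quantity": "Unfolding",
                    "value": unfolding_percent(curve), "se": np.nan, "units": "%"})
            except ValueError:
                pass  # window does not span 20-96 deg C
        elif assay == "sec":
            column = SECColumn(v_total=cfg["v_total_mL"], v_void=cfg["v_void_mL"])
            std = _read_csv(cfg["standards"], "sec_standards")
            dc_std = [distribution_coefficient(v, column) for v in std["v_elute_mL"]]
            cal = CalibrationCurve.from_standards(std["mw_kDa"].to_numpy(), dc_std)
            runs = _read_csv(cfg["data"], "sec")
            for _, row in runs.iterrows():
                dc = distribution_coefficient(float(row["v_elute_mL"]), column)
                mw = estimate_mw(dc, cal)
                bundle["rows"].append({"variant": str(row["sample"]), "quantity": "MW",
                                       "value": mw, "se": np.nan, "units": "kDa"})
        else:
            raise ValueError(f"unknown assay {assay!r}")
    except (FileNotFoundError, ParseError, ValueError) as exc:
        bundle["ok"] = False
        bundle["error"] = str(exc)
        log.error("pipeline failed: %s", exc)
        return bundle

    df = pd.DataFrame(bundle["rows"])
    df.to_csv(out_dir / "report.csv", index=False)
    with open(out_dir / "report.txt", "w", encoding="utf-8") as fh:
        fh.write(f"casensor {__version__} — assay: {assay}\n")
        for r in bundle["rows"]:
            disp = r.get("display")
            val = disp if disp else (f"{r['value']:.4g}" if r["value"] == r["value"] else "nan")
            se = f" ± {r['se']:.2g}" if r["se"] == r["se"] else ""
            fh.write(f"  {r['variant']:>8s}  {r['quantity']:>10s} = {val}{se} {r['units']}\n")
    with open(out_dir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(bundle["log"], fh, indent=2, default=str)
    return bundle
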
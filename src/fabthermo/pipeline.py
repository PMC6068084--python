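"""End-to-end analysis: sensorgrams (or rate tables) to a variant report.

A pipeline configuration lists variants, each backed either by sensorgram
files grouped by temperature (fitted with the 1:1 Langmuir global fit) or
by an already-determined per-temperature rate table ("fit bypass" mode,
for working directly from published kinetic constants).  Exactly one
variant is flagged as the reference; every variant's kon and koff are
reported as fold changes against it.

Per variant the report carries: Kd, kon +/- SE and koff +/- SE at the
report temperature; the van't Hoff parameters dH, dS, dCp (>= 3
temperatures required); the Eyring activation parameters dH_act, dS_act
(>= 2 temperatures); the qualitative enthalpy/entropy signature; and the
fold changes.  Variants measured at a single temperature get kinetics only,
with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import blank_subtract, global_fit, sigfig
from .io import read_sensorgram
from .thermo import (
    ActivationParams,
    ThermoParams,
    classify_signature,
    eyring_fit,
    fold_change,
    gibbs_from_kd,
    vant_hoff_fit,
)

logger = logging.getLogger("fabthermo")

DEFAULT_REPORT_TEMPERATURE = 298.15


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class VariantResult:
    """Everything computed for one variant."""

    name: str
    rates: pd.DataFrame  # columns: temperature_K, kon, koff, kon_se, koff_se
    report_row: pd.Series
    thermo: ThermoParams | None = None
    activation: ActivationParams | None = None
    signature: dict[str, str] | None = None
    fold_kon: float | None = None
    fold_koff: float | None = None

    @property
    def kd(self) -> float:
        return float(self.report_row["koff"] / self.report_row["kon"])


def _rates_from_traces(entries: list[dict], base_dir: Path) -> pd.DataFrame:
    rows = []
    for entry in entries:
        temp = float(entry["temperature_K"])
        traces = [read_sensorgram(base_dir / f) for f in entry["samples"]]
        if "blank" in entry and entry["blank"]:
            blank = read_sensorgram(base_dir / entry["blank"])
            traces = [blank_subtract(tr, blank) for tr in traces]
        fit = global_fit(traces)
        if not fit.converged:
            raise RuntimeError(f"global fit did not converge at T={temp} K")
        rows.append(
            {
                "temperature_K": temp,
                "kon": fit.params.kon,
                "koff": fit.params.koff,
                "kon_se": fit.standard_errors["kon"],
                "koff_se": fit.standard_errors["koff"],
            }
        )
    return pd.DataFrame(rows)


def _rates_from_table(entries: list[dict]) -> pd.DataFrame:
    rows = []
    for entry in entries:
        rows.append(
            {
                "temperature_K": float(entry["temperature_K"]),
                "kon": float(entry["kon"]),
                "koff": float(entry["koff"]),
                "kon_se": float(entry.get("kon_se", np.nan)),
                "koff_se": float(entry.get("koff_se", np.nan)),
            }
        )
    return pd.DataFrame(rows)


def analyze_variant(
    name: str, rates: pd.DataFrame, report_temperature: float = DEFAULT_REPORT_TEMPERATURE
) -> VariantResult:
    """Thermodynamic work-up of one variant's per-temperature rate table."""
    rates = rates.sort_values("temperature_K").reset_index(drop=True)
    i_report = int((rates["temperature_K"] - report_temperature).abs().idxmin())
    report_row = rates.loc[i_report]

    n_temps = rates["temperature_K"].nunique()
    thermo = activation = signature = None
    if n_temps >= 2:
        activation = eyring_fit(rates["temperature_K"].values, rates["kon"].values)
    if n_temps >= 3:
        dg = gibbs_from_kd(rates["koff"].values / rates["kon"].values, rates["temperature_K"].values)
        thermo = vant_hoff_fit(rates["temperature_K"].values, dg)
        signature = classify_signature(thermo.dH, thermo.dS)
    else:
        warnings.warn(
            f"variant {name!r}: only {n_temps} temperature(s); "
            "reporting kinetics only, thermodynamics skipped",
            RuntimeWarning,
            stacklevel=2,
        )
    return VariantResult(
        name=name, rates=rates, report_row=report_row,
        thermo=thermo, activation=activation, signature=signature,
    )


def run_pipeline(config: dict, base_dir=".") -> pd.DataFrame:
    """Run the full analysis described by a configuration mapping.

    Returns the report table (one row per variant).  ``base_dir`` anchors
    relative trace-file paths.
    """
    base_dir = Path(base_dir)
    variants_cfg = config.get("variants")
    if not variants_cfg:
        raise ConfigError("config must list at least one variant under 'variants'")
    reference = config.get("reference")
    if not reference:
        raise ConfigError("config must name a 'reference' variant")
    names = [v.get("name") for v in variants_cfg]
    if reference not in names:
        raise ConfigError(f"reference variant {reference!r} not among variants {names}")
    report_temperature = float(config.get("report_temperature_K", DEFAULT_REPORT_TEMPERATURE))

    results: dict[str, VariantResult] = {}
    for vcfg in variants_cfg:
        name = vcfg["name"]
        logger.info("analyzing variant %s", name)
        if "rates" in vcfg:
            rates = _rates_from_table(vcfg["rates"])
        elif "traces" in vcfg:
            rates = _rates_from_traces(vcfg["traces"], base_dir)
        else:
            raise ConfigError(f"variant {name!r} supplies neither 'rates' nor 'traces'")
        results[name] = analyze_variant(name, rates, report_temperature)

    ref = results[reference].report_row
    rows = []
    for name in names:
        res = results[name]
        res.fold_kon = fold_change(float(res.report_row["kon"]), float(ref["kon"]))
        res.fold_koff = fold_change(float(res.report_row["koff"]), float(ref["koff"]))
        row = {
            "variant": name,
            "temperature_K": float(res.report_row["temperature_K"]),
            "kd_M": res.kd,
            "kon": float(res.report_row["kon"]),
            "kon_se": float(res.report_row["kon_se"]),
            "koff": float(res.report_row["koff"]),
            "koff_se": float(res.report_row["koff_se"]),
            "fold_kon": res.fold_kon,
            "fold_koff": res.fold_koff,
        }
        if res.thermo is not None:
            row.update(
                dH_J_mol=res.thermo.dH, dS_J_mol_K=res.thermo.dS, dCp_J_mol_K=res.thermo.dCp,
                enthalpy=res.signature["enthalpy"], entropy=res.signature["entropy"],
            )
        if res.activation is not None:
            row.update(dH_act_J_mol=res.activation.dH_act, dS_act_J_mol_K=res.activation.dS_act)
        rows.append(row)
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> str:
    """Human-readable report at 3 significant figures."""
    lines = []
    has_thermo = "dH_J_mol" in report.columns
    for _, row in report.iterrows():
        lines.append(f"{row['variant']}:")
        lines.append(
            f"  Kd = {sigfig(row['kd_M']):.3g} M   "
            f"kon = {sigfig(row['kon']):.3g} +/- {sigfig(row['kon_se']):.3g} M^-1 s^-1   "
            f"koff = {sigfig(row['koff']):.3g} +/- {sigfig(row['koff_se']):.3g} s^-1"
        )
        lines.append(
            f"  fold vs reference: kon x{row['fold_kon']:.2g}, koff x{row['fold_koff']:.2g}"
        )
        if has_thermo and pd.notna(row.get("dH_J_mol")):
            lines.append(
                f"  dH = {sigfig(row['dH_J_mol'] / 1e3):.3g} kJ/mol ({row['enthalpy']})   "
                f"dS = {sigfig(row['dS_J_mol_K']):.3g} J/mol/K ({row['entropy']})   "
                f"dCp = {sigfig(row['dCp_J_mol_K']):.3g} J/mol/K"
            )
        if "dH_act_J_mol" in report.columns and pd.notna(row.get("dH_act_J_mol")):
            lines.append(
                f"  dH_act = {sigfig(row['dH_act_J_mol'] / 1e3):.3g} kJ/mol   "
                f"dS_act = {sigfig(row['dS_act_J_mol_K']):.3g} J/mol/K"
            )
    return "\n".join(lines)
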
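"""Thermodynamically self-consistent synthetic SPR/DSC experiments.

No raw sensorgram data accompany the Fab panel this package targets, so
every pipeline stage is exercised on generated experiments instead.  The
generator is built to be self-consistent across temperature: a ground
truth is specified by equilibrium thermodynamics (dH, dS, dCp) plus Eyring
activation parameters for association, from which

    kon(T)  = (kB*T/h) * exp(dS_act/R - dH_act/(R*T))
    Kd(T)   = exp(dG(T) / (R*T)),  dG from the van't Hoff model
    koff(T) = kon(T) * Kd(T)

so the thermodynamic cycle closes exactly at every temperature: fitting
the generated rate constants back through the van't Hoff and Eyring
analyses must recover the generating parameters.

The default experiment design mirrors a Biacore-style campaign on a
sub-nanomolar Fab: five temperatures from 283.15 to 303.15 K, a
concentration series {1.25, 2.5, 5, 10} nM bracketing the typical assay
concentration of 5 nM, 120 s association / 600 s dissociation sampled at
1 Hz, one blank cycle per temperature, and i.i.d. Gaussian RU noise.
Rmax is held constant across temperatures (a single immobilized surface).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import InjectionProtocol, KineticParams, SensorgramTrace, simulate_sensorgram
from .charge import ChainSequence, apply_mutations, parse_mutation
from .constants import R
from .reference import KINETICS_25C, mutation_tokens
from .thermo import ActivationParams, ThermoParams, eyring_kon, kd_from_gibbs, predict_gibbs

#: The five standard assay temperatures, K.
DEFAULT_TEMPERATURES = (283.15, 288.15, 293.15, 298.15, 303.15)

#: Default analyte concentration series, M.
DEFAULT_CONCENTRATIONS = (1.25e-9, 2.5e-9, 5e-9, 10e-9)


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters plus the derived per-temperature rate table."""

    thermo: ThermoParams
    activation_on: ActivationParams
    rmax: float = 100.0

    def kon(self, temperature: float | np.ndarray) -> float | np.ndarray:
        return eyring_kon(self.activation_on, temperature)

    def kd(self, temperature: float | np.ndarray) -> float | np.ndarray:
        return kd_from_gibbs(predict_gibbs(self.thermo, temperature), temperature)

    def koff(self, temperature: float | np.ndarray) -> float | np.ndarray:
        return self.kon(temperature) * self.kd(temperature)

    def kinetic_params(self, temperature: float) -> KineticParams:
        return KineticParams(
            kon=float(self.kon(temperature)),
            koff=float(self.koff(temperature)),
            rmax=self.rmax,
            temperature=temperature,
        )

    def table(self, temperatures=DEFAULT_TEMPERATURES) -> pd.DataFrame:
        t = np.asarray(temperatures, dtype=float)
        return pd.DataFrame(
            {"temperature_K": t, "kon": self.kon(t), "koff": self.koff(t), "kd": self.kd(t)}
        )


def consistent_ground_truth(
    thermo: ThermoParams,
    activation_on: ActivationParams,
    temperatures=DEFAULT_TEMPERATURES,
    rmax: float = 100.0,
) -> GroundTruth:
    """Assemble a ground truth and sanity-check the implied rate regime."""
    truth = GroundTruth(thermo=thermo, activation_on=activation_on, rmax=rmax)
    kon = np.asarray(truth.kon(np.asarray(temperatures, dtype=float)))
    if np.any(kon < 1.0) or np.any(kon > 1e12):
        warnings.warn(
            f"kon outside the plausible SPR regime [1, 1e12] M^-1 s^-1 "
            f"(range {kon.min():.3g}..{kon.max():.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return truth


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of a multi-temperature, multi-concentration SPR campaign."""

    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    t_assoc_end: float = 120.0
    t_end: float = 720.0
    sample_interval: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.temperatures)) != len(self.temperatures):
            raise ValueError("design temperatures must be distinct")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be >= 0")
        if sum(c > 0 for c in self.concentrations) < 2:
            raise ValueError("need >= 2 positive concentrations")

    def protocol(self, concentration: float) -> InjectionProtocol:
        return InjectionProtocol(
            t_assoc_start=0.0,
            t_assoc_end=self.t_assoc_end,
            t_end=self.t_end,
            concentration=concentration,
            sample_interval=self.sample_interval,
        )


def simulate_campaign(
    truth: GroundTruth, design: ExperimentDesign
) -> dict[float, dict[str, SensorgramTrace | list[SensorgramTrace]]]:
    """Simulate every cycle of the campaign, in memory.

    Returns ``{temperature: {"blank": trace, "traces": [trace, ...]}}``.
    The blank is a zero-concentration cycle carrying only noise.  A single
    seeded generator is consumed in a fixed order, so a fixed design seed
    reproduces the campaign exactly.
    """
    rng = np.random.default_rng(design.seed)
    campaign: dict[float, dict] = {}
    for temp in design.temperatures:
        kp = truth.kinetic_params(temp)
        blank = simulate_sensorgram(
            kp, design.protocol(0.0), noise_sd=design.noise_sd, seed=rng, label="blank"
        )
        traces = [
            simulate_sensorgram(
                kp, design.protocol(c), noise_sd=design.noise_sd, seed=rng, label=f"C={c:g}M"
            )
            for c in design.concentrations
        ]
        campaign[temp] = {"blank": blank, "traces": traces}
    return campaign


def generate_experiment(truth: GroundTruth, design: ExperimentDesign, out_dir) -> dict:
    """Write the campaign as sensorgram CSV files plus a YAML manifest.

    One file per (temperature, concentration) cycle and one blank per
    temperature.  The manifest records the generating parameters and the
    derived per-temperature rate constants so downstream recovery tests are
    self-describing.  Returns the manifest dict.
    """
    from pathlib import Path

    from .io import write_manifest, write_sensorgram

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    campaign = simulate_campaign(truth, design)

    files: list[dict] = []
    for temp, group in campaign.items():
        blank_name = f"T{temp:.2f}_blank.csv"
        write_sensorgram(group["blank"], out / blank_name)
        entry = {"temperature_K": float(temp), "blank": blank_name, "samples": []}
        for trace in group["traces"]:
            name = f"T{temp:.2f}_C{trace.concentration:.3e}.csv"
            write_sensorgram(trace, out / name)
            entry["samples"].append(name)
        files.append(entry)

    table = truth.table(design.temperatures)
    manifest = {
        "truth": {
            "dH": truth.thermo.dH,
            "dS": truth.thermo.dS,
            "dCp": truth.thermo.dCp,
            "dH_act": truth.activation_on.dH_act,
            "dS_act": truth.activation_on.dS_act,
            "rmax": truth.rmax,
            "rates": table.to_dict(orient="records"),
        },
        "design": {
            "temperatures_K": [float(t) for t in design.temperatures],
            "concentrations_M": [float(c) for c in design.concentrations],
            "t_assoc_end_s": design.t_assoc_end,
            "t_end_s": design.t_end,
            "sample_interval_s": design.sample_interval,
            "noise_sd_RU": design.noise_sd,
            "seed": design.seed,
        },
        "files": files,
    }
    write_manifest(manifest, out / "manifest.yaml")
    return manifest


# ---------------------------------------------------------------------------
# Panel presets
# ---------------------------------------------------------------------------

#: Binding enthalpy at 293.15 K (J mol^-1) for each panel variant: positive
#: (entropy-driven binding) for the wild type and acidic mutants, negative
#: (additional favorable electrostatics) for the basic mutants.
_PRESET_DH = {
    "wild-type": 15e3, "D5": 15e3, "E5": 15e3,
    "R3": -20e3, "R5": -25e3, "K5": -15e3,
}

#: Activation enthalpy of association (J mol^-1): low (favorable) for the
#: R5 encounter complex, high (unfavorable) for K5, intermediate otherwise.
_PRESET_DH_ACT = {
    "wild-type": 35e3, "R3": 30e3, "R5": 12e3, "K5": 55e3, "D5": 35e3, "E5": 35e3,
}

#: Heat-capacity change of binding (J mol^-1 K^-1), typical of a
#: protein-protein interface.
_PRESET_DCP = -800.0

_T_OBS = 298.15  # temperature at which the panel constants were measured


def variant_ground_truth(variant: str, rmax: float = 100.0) -> GroundTruth:
    """Self-consistent ground truth anchored to a panel variant's constants.

    The activation entropy is solved so the Eyring model reproduces the
    variant's measured kon at 298.15 K, and the binding entropy so the
    van't Hoff model reproduces its measured Kd there; the preset dH, dH_act
    and dCp encode the qualitative thermodynamic signatures of the panel.
    """
    if variant not in KINETICS_25C:
        raise KeyError(f"unknown panel variant {variant!r}")
    ref = KINETICS_25C[variant]
    from .constants import H as PLANCK, KB, T_REF

    dH_act = _PRESET_DH_ACT[variant]
    dS_act = R * (np.log(ref["kon"] * PLANCK / (KB * _T_OBS)) + dH_act / (R * _T_OBS))

    dH = _PRESET_DH[variant]
    dG_obs = R * _T_OBS * np.log(ref["kd"])
    cp_terms = _PRESET_DCP * (_T_OBS - T_REF) - _PRESET_DCP * _T_OBS * np.log(_T_OBS / T_REF)
    dS = (dH + cp_terms - dG_obs) / _T_OBS

    return consistent_ground_truth(
        ThermoParams(dH=dH, dS=float(dS), dCp=_PRESET_DCP),
        ActivationParams(dH_act=dH_act, dS_act=float(dS_act)),
        rmax=rmax,
    )


# ---------------------------------------------------------------------------
# DSC thermograms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Thermogram:
    """A DSC scan: temperatures (degC) and excess heat capacity (J mol^-1 K^-1)."""

    temps_c: np.ndarray
    excess_cp: np.ndarray


def generate_dsc_thermogram(
    tm_c: float,
    dH_unf: float = 400e3,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Thermogram:
    """Two-state van't Hoff excess heat capacity with a peak near ``tm_c``.

    With equilibrium constant K(T) = exp(-dH_unf/R * (1/T - 1/Tm)) the
    two-state excess heat capacity is

        Cp_ex(T) = dH_unf**2 / (R*T**2) * K / (1 + K)**2

    which peaks within a few hundredths of a degree of Tm for realistic
    unfolding enthalpies; larger ``dH_unf`` gives a narrower peak.  The
    default grid is 30-90 degC at 0.1 degC, the usual protein DSC window.
    """
    if grid is None:
        grid = np.linspace(30.0, 90.0, 601)
    grid = np.asarray(grid, dtype=float)
    if not grid[0] <= tm_c <= grid[-1]:
        raise ValueError(f"tm_c={tm_c} lies outside the scan range [{grid[0]}, {grid[-1]}] degC")
    if dH_unf <= 0:
        raise ValueError("dH_unf must be positive")

    t_k = grid + 273.15
    tm_k = tm_c + 273.15
    ln_k = -dH_unf / R * (1.0 / t_k - 1.0 / tm_k)
    k_eq = np.exp(ln_k)
    cp = dH_unf**2 / (R * t_k**2) * k_eq / (1.0 + k_eq) ** 2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cp = cp + rng.normal(0.0, noise_sd * float(np.max(cp)), size=cp.shape)
    return Thermogram(temps_c=grid, excess_cp=cp)


# ---------------------------------------------------------------------------
# Demo light chain
# ---------------------------------------------------------------------------

_VL_SCAFFOLD = (
    "DIVMTQSPSSLAVSAGEKVTMSCKSSQSLLNSRTRKNYLAWYQQKPGQSPKLLIYWASTRES"
    "GVPDRFTGSGSGTDFTLTISSVQAEDLAVYYCKQSYNLYTFGGGTKLEIK"
)


def demo_vl() -> ChainSequence:
    """Synthetic kappa light-chain variable domain for charge demos.

    A generic VL scaffold with serines placed at sequential positions 63,
    65, 67, 70 and 72 (the framework-3 positions the panel mutates).  It is
    a constructed demo sequence, not the panel antibody's real chain, which
    was never deposited in machine-readable form.
    """
    residues = list(_VL_SCAFFOLD)
    for pos in (63, 65, 67, 70, 72):
        residues[pos - 1] = "S"
    return ChainSequence(identifier="demo-VL", residues="".join(residues))


def panel_mutant(wildtype: ChainSequence, variant: str) -> ChainSequence:
    """Build a panel mutant (R3/R5/K5/D5/E5) from a wild-type light chain."""
    specs = [parse_mutation(tok) for tok in mutation_tokens(variant)]
    if not specs:
        return wildtype
    return apply_mutations(wildtype, specs, identifier=f"{wildtype.identifier}-{variant}")
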
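"""Equilibrium and transition-state thermodynamics of binding.

Equilibrium side: the standard-state Gibbs energy of binding follows from
the dissociation constant, ``dG = R*T*ln(Kd)`` (Kd in M, so dG < 0 for
sub-molar affinity).  Its temperature dependence is described by the
nonlinear van't Hoff relation with a temperature-independent heat-capacity
change dCp, anchored at the reference temperature T0 = 293.15 K:

    dG(T) = dH - T*dS + dCp*(T - T0) - dCp*T*ln(T/T0)

Although commonly called "nonlinear" (it is nonlinear in T), the model is
linear in (dH, dS, dCp), so the fit is an exact linear least-squares solve.

Transition-state side: the Eyring approximation relates the temperature
dependence of the association rate constant to activation parameters,

    ln(kon/T) = -dH_act/(R*T) + dS_act/R + ln(kB/h)

fitted here as an ordinary least-squares line of ln(kon/T) on 1/T.

Also provided: fold-change ratios between variants, a qualitative
classification of thermodynamic signatures (enthalpy/entropy driven), and
melting-temperature extraction from DSC-style excess heat-capacity
thermograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import R, KB, H, T_REF


@dataclass(frozen=True)
class ThermoParams:
    """Equilibrium binding thermodynamics at the 293.15 K reference.

    dH (J mol^-1) and dS (J mol^-1 K^-1) are the binding enthalpy and
    entropy changes at 293.15 K; dCp (J mol^-1 K^-1) is assumed
    temperature-independent.  The reference temperature is fixed by the
    model parameterization and is not configurable.
    """

    dH: float
    dS: float
    dCp: float = 0.0

    t_ref: float = T_REF

    def __post_init__(self) -> None:
        if self.t_ref != T_REF:
            raise ValueError(f"reference temperature is fixed at {T_REF} K")


@dataclass(frozen=True)
class ActivationParams:
    """Eyring activation enthalpy (J mol^-1) and entropy (J mol^-1 K^-1)."""

    dH_act: float
    dS_act: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dH_act) and np.isfinite(self.dS_act)):
            raise ValueError("activation parameters must be finite")


def gibbs_from_kd(kd: float | np.ndarray, temperature: float | np.ndarray) -> float | np.ndarray:
    """Standard-state binding Gibbs energy R*T*ln(Kd), J mol^-1 (Kd in M)."""
    kd = np.asarray(kd, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    if np.any(kd <= 0):
        raise ValueError("kd must be positive (M)")
    if np.any(temperature <= 0):
        raise ValueError("temperature must be positive (K)")
    out = R * temperature * np.log(kd)
    return float(out) if out.ndim == 0 else out


def kd_from_gibbs(dG: float | np.ndarray, temperature: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`gibbs_from_kd`: Kd = exp(dG/(R*T)), M."""
    out = np.exp(np.asarray(dG, dtype=float) / (R * np.asarray(temperature, dtype=float)))
    return float(out) if out.ndim == 0 else out


def predict_gibbs(params: ThermoParams, temperature: float | np.ndarray) -> float | np.ndarray:
    """van't Hoff dG(T) with heat-capacity curvature, J mol^-1.

    At T = 293.15 K both dCp terms vanish and the expression reduces to
    dH - T*dS exactly.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (K)")
    out = (
        params.dH
        - t * params.dS
        + params.dCp * (t - T_REF)
        - params.dCp * t * np.log(t / T_REF)
    )
    return float(out) if out.ndim == 0 else out


def vant_hoff_fit(temperatures: np.ndarray, dG: np.ndarray) -> ThermoParams:
    """Fit (dH, dS, dCp) to (T, dG) points by least squares.

    Requires at least three distinct temperatures (three parameters).  The
    design matrix is [1, -T, (T - T0) - T*ln(T/T0)]; points are unweighted.
    """
    t = np.asarray(temperatures, dtype=float)
    g = np.asarray(dG, dtype=float)
    if t.shape != g.shape:
        raise ValueError("temperatures and dG must have matching shapes")
    if np.unique(t).size < 3:
        raise ValueError("need >= 3 distinct temperatures to fit dH, dS and dCp")
    design = np.column_stack([np.ones_like(t), -t, (t - T_REF) - t * np.log(t / T_REF)])
    coef, *_ = np.linalg.lstsq(design, g, rcond=None)
    return ThermoParams(dH=float(coef[0]), dS=float(coef[1]), dCp=float(coef[2]))


def eyring_fit(temperatures: np.ndarray, kon: np.ndarray) -> ActivationParams:
    """Activation parameters from the temperature dependence of kon.

    Ordinary least squares of ln(kon/T) on 1/T: the slope is -dH_act/R and
    the intercept is dS_act/R + ln(kB/h).
    """
    t = np.asarray(temperatures, dtype=float)
    k = np.asarray(kon, dtype=float)
    if t.shape != k.shape:
        raise ValueError("temperatures and kon must have matching shapes")
    if np.unique(t).size < 2:
        raise ValueError("need >= 2 distinct temperatures for an Eyring fit")
    if np.any(k <= 0) or np.any(t <= 0):
        raise ValueError("kon and temperatures must be positive")
    slope, intercept = np.polyfit(1.0 / t, np.log(k / t), 1)
    return ActivationParams(dH_act=float(-slope * R), dS_act=float((intercept - np.log(KB / H)) * R))


def eyring_kon(activation: ActivationParams, temperature: float | np.ndarray) -> float | np.ndarray:
    """Association rate constant predicted by the Eyring model, M^-1 s^-1."""
    t = np.asarray(temperature, dtype=float)
    out = (KB * t / H) * np.exp(activation.dS_act / R - activation.dH_act / (R * t))
    return float(out) if out.ndim == 0 else out


def fold_change(mutant_value: float, wildtype_value: float) -> float:
    """Ratio mutant/wild-type of a (positive) kinetic constant."""
    if wildtype_value <= 0:
        raise ValueError("wild-type value must be positive")
    if mutant_value < 0:
        raise ValueError("mutant value must be non-negative")
    return mutant_value / wildtype_value


#: neutrality tolerance on |dH| and |T*dS|, J mol^-1 (0.1 kJ mol^-1)
SIGNATURE_TOL = 100.0


def classify_signature(
    dH: float, dS: float, temperature: float = T_REF, tol: float = SIGNATURE_TOL
) -> dict[str, str]:
    """Label the enthalpic and entropic contributions to binding.

    The enthalpy term is favorable when dH < 0; the entropy term when
    -T*dS < 0, i.e. dS > 0.  Contributions smaller than ``tol`` in absolute
    energy are labelled neutral.
    """
    if not (np.isfinite(dH) and np.isfinite(dS)):
        raise ValueError("dH and dS must be finite")

    def label(energy: float) -> str:
        if abs(energy) < tol:
            return "neutral"
        return "favorable" if energy < 0 else "unfavorable"

    return {"enthalpy": label(dH), "entropy": label(-temperature * dS)}


@dataclass(frozen=True)
class TmResult:
    """Melting temperature extracted from a thermogram, degC."""

    tm_c: float
    at_edge: bool = False


def tm_from_thermogram(temps_c: np.ndarray, excess_cp: np.ndarray) -> TmResult:
    """Melting temperature = peak of the baseline-subtracted excess Cp.

    The baseline is the straight line through the pre- and post-transition
    plateaus (means of the first and last three points).  The peak position
    is refined by parabolic interpolation through the three points around
    the grid argmax.  A curve with no discernible interior peak raises
    ``ValueError``; a maximum sitting on the grid edge is returned with
    ``at_edge=True`` and a warning.
    """
    t = np.asarray(temps_c, dtype=float)
    cp = np.asarray(excess_cp, dtype=float)
    if t.shape != cp.shape or t.size < 5:
        raise ValueError("need matching grids of >= 5 points spanning the peak")

    n_edge = 3
    t0, t1 = float(np.mean(t[:n_edge])), float(np.mean(t[-n_edge:]))
    c0, c1 = float(np.mean(cp[:n_edge])), float(np.mean(cp[-n_edge:]))
    baseline = c0 + (c1 - c0) * (t - t0) / (t1 - t0)
    signal = cp - baseline

    peak = float(np.max(signal))
    scale = max(float(np.max(np.abs(cp))), 1.0)
    if peak <= 1e-9 * scale:
        raise ValueError("no transition peak found in thermogram")

    i = int(np.argmax(signal))
    if i == 0 or i == t.size - 1:
        warnings.warn("thermogram peak lies on the grid edge", RuntimeWarning, stacklevel=2)
        return TmResult(tm_c=float(t[i]), at_edge=True)

    # parabolic refinement for sub-grid-step accuracy
    y0, y1, y2 = signal[i - 1], signal[i], signal[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom < 0:
        frac = 0.5 * (y0 - y2) / denom
        tm = float(t[i] + frac * (t[i + 1] - t[i]))
    else:
        tm = float(t[i])
    return TmResult(tm_c=tm, at_edge=False)
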
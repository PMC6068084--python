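"""Blank subtraction and global 1:1 Langmuir fitting of sensorgram sets.

A concentration series measured at one temperature is fitted jointly: a
single (kon, koff, Rmax) triple must explain every trace, with each trace
evaluated at its own analyte concentration and phase boundaries.  The
optimisation runs on log10-transformed parameters, which enforces
positivity and conditions the problem (rate constants span several orders
of magnitude), via :mod:`lmfit` (Levenberg–Marquardt).  Standard errors
come from the Jacobian-based covariance with the usual residual-variance
estimate, matching the "mean ± SE" convention of instrument software
reports without bootstrap cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .binding import KineticParams, InjectionProtocol, SensorgramTrace, simulate_clean

#: relative-RSS convergence / termination tolerances for the least-squares run
_FIT_TOL = 1e-12
_MAX_ITER = 500

LN10 = np.log(10.0)


class NonIdentifiableError(ValueError):
    """Raised when the trace set cannot pin down the kinetic parameters."""


@dataclass
class FitResult:
    """Outcome of a global fit.

    ``standard_errors`` maps ``kon``/``koff``/``rmax`` to SEs in the same
    units as the parameter itself.  ``warnings`` collects soft diagnostics,
    e.g. a dissociation phase too short to determine koff.
    """

    params: KineticParams
    standard_errors: dict[str, float]
    residual_sum_of_squares: float
    n_points: int
    converged: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def kd(self) -> float:
        return self.params.kd


def blank_subtract(sample: SensorgramTrace, blank: SensorgramTrace) -> SensorgramTrace:
    """Subtract a blank-cell trace from a sample trace point by point.

    The two traces must share the exact same time grid; no interpolation is
    attempted. Metadata (concentration, temperature, phases) is copied from
    the sample.
    """
    if not np.array_equal(sample.times, blank.times):
        raise ValueError("sample and blank time grids differ; refusing to interpolate")
    return SensorgramTrace(
        times=sample.times.copy(),
        responses=sample.responses - blank.responses,
        concentration=sample.concentration,
        temperature=sample.temperature,
        t_assoc_start=sample.t_assoc_start,
        t_assoc_end=sample.t_assoc_end,
        label=sample.label,
    )


def _protocol_for(trace: SensorgramTrace) -> InjectionProtocol:
    return InjectionProtocol(
        t_assoc_start=trace.t_assoc_start,
        t_assoc_end=trace.t_assoc_end,
        t_end=trace.times[-1] + 1.0,
        concentration=trace.concentration,
    )


def _initial_guess(traces: list[SensorgramTrace]) -> tuple[float, float, float]:
    """Deterministic, derivative-free starting point.

    koff from a log-linear regression of the dissociation tail of the
    highest-concentration trace; kobs per trace from the time to half of the
    end-of-injection response, whence kon; rmax from the largest observed
    response times 1.2.
    """
    rmax0 = 1.2 * max(float(np.max(tr.responses)) for tr in traces)
    if rmax0 <= 0:
        rmax0 = 1.0

    top = max(traces, key=lambda tr: tr.concentration)
    koff0 = 1e-3
    mask = (top.times > top.t_assoc_end) & (top.responses > 1e-3 * rmax0)
    if np.count_nonzero(mask) >= 3:
        slope = np.polyfit(top.times[mask], np.log(top.responses[mask]), 1)[0]
        if slope < 0:
            koff0 = -slope
    koff0 = float(np.clip(koff0, 1e-7, 1.0))

    kon_estimates = []
    for tr in traces:
        if tr.concentration <= 0:
            continue
        assoc = tr.times <= tr.t_assoc_end
        if np.count_nonzero(assoc) < 3:
            continue
        t_a = tr.times[assoc] - tr.t_assoc_start
        r_a = tr.responses[assoc]
        plateau = r_a[-1]
        if plateau <= 0:
            continue
        above = np.nonzero(r_a >= 0.5 * plateau)[0]
        if above.size == 0 or t_a[above[0]] <= 0:
            continue
        kobs = np.log(2.0) / t_a[above[0]]
        kon_estimates.append(max(kobs - koff0, 0.1 * kobs) / tr.concentration)
    kon0 = float(np.exp(np.mean(np.log(kon_estimates)))) if kon_estimates else 1e6
    kon0 = float(np.clip(kon0, 1.0, 1e12))
    return kon0, koff0, rmax0


def global_fit(traces: list[SensorgramTrace] | SensorgramTrace) -> FitResult:
    """Globally fit kon, koff and Rmax to a one-temperature trace set.

    All traces must share the same temperature; at least one must have a
    positive analyte concentration and a non-trivial response, otherwise the
    parameters are not identifiable.
    """
    if isinstance(traces, SensorgramTrace):
        traces = [traces]
    traces = list(traces)
    if not traces:
        raise NonIdentifiableError("no traces supplied")
    temps = {tr.temperature for tr in traces}
    if len(temps) != 1:
        raise ValueError(f"traces span multiple temperatures: {sorted(temps)}")
    if all(tr.concentration <= 0 for tr in traces):
        raise NonIdentifiableError("no trace with positive analyte concentration")
    if max(float(np.max(np.abs(tr.responses))) for tr in traces) == 0.0:
        raise NonIdentifiableError("all responses are zero; nothing to fit")

    temperature = traces[0].temperature
    kon0, koff0, rmax0 = _initial_guess(traces)

    pars = lmfit.Parameters()
    pars.add("log10_kon", value=np.log10(kon0), min=-2, max=14)
    pars.add("log10_koff", value=np.log10(koff0), min=-9, max=2)
    pars.add("log10_rmax", value=np.log10(rmax0), min=np.log10(rmax0) - 4, max=np.log10(rmax0) + 4)

    protocols = [_protocol_for(tr) for tr in traces]

    def residuals(p: lmfit.Parameters) -> np.ndarray:
        kp = KineticParams(
            kon=10.0 ** p["log10_kon"].value,
            koff=10.0 ** p["log10_koff"].value,
            rmax=10.0 ** p["log10_rmax"].value,
            temperature=temperature,
        )
        return np.concatenate(
            [tr.responses - simulate_clean(kp, proto, tr.times) for tr, proto in zip(traces, protocols)]
        )

    minimizer = lmfit.Minimizer(residuals, pars)
    out = minimizer.minimize(
        method="leastsq", xtol=_FIT_TOL, ftol=_FIT_TOL, gtol=_FIT_TOL, max_nfev=_MAX_ITER * 10
    )

    fitted = KineticParams(
        kon=10.0 ** out.params["log10_kon"].value,
        koff=10.0 ** out.params["log10_koff"].value,
        rmax=10.0 ** out.params["log10_rmax"].value,
        temperature=temperature,
    )

    ses: dict[str, float] = {}
    for name, value in (("kon", fitted.kon), ("koff", fitted.koff), ("rmax", fitted.rmax)):
        stderr = out.params[f"log10_{name}"].stderr
        # delta method: SE(x) = x * ln(10) * SE(log10 x)
        ses[name] = float(value * LN10 * stderr) if stderr is not None else float("nan")

    notes: list[str] = []
    dissoc_duration = max(float(tr.times[-1] - tr.t_assoc_end) for tr in traces)
    if fitted.koff * dissoc_duration < 1e-3:
        notes.append(
            "koff poorly determined: koff * dissociation duration "
            f"= {fitted.koff * dissoc_duration:.2e} < 1e-3"
        )
        warnings.warn(notes[-1], RuntimeWarning, stacklevel=2)

    return FitResult(
        params=fitted,
        standard_errors=ses,
        residual_sum_of_squares=float(np.sum(out.residual**2)),
        n_points=int(out.ndata),
        converged=bool(out.success),
        warnings=notes,
    )


def sigfig(x: float, n: int = 3) -> float:
    """Round ``x`` to ``n`` significant figures."""
    if x == 0 or not np.isfinite(x):
        return x
    return float(f"{x:.{n - 1}e}")


def fit_report(result: FitResult, variant: str = "") -> dict[str, float | str]:
    """One table row of kinetic constants at reporting precision.

    Kd is the ratio of the 3-significant-figure rounded rate constants, the
    convention used in instrument-software kinetic tables; Rmax is internal
    and excluded from the row.
    """
    if not result.converged:
        raise ValueError("cannot report an unconverged fit")
    kon = sigfig(result.params.kon, 3)
    koff = sigfig(result.params.koff, 3)
    return {
        "variant": variant,
        "kd_M": sigfig(koff / kon, 3),
        "kon_M-1s-1": kon,
        "kon_se": sigfig(result.standard_errors["kon"], 3),
        "koff_s-1": koff,
        "koff_se": sigfig(result.standard_errors["koff"], 3),
    }
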
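"""1:1 Langmuir interaction model for SPR sensorgrams.

The reversible bimolecular reaction A + B <=> AB observed on a Biacore-style
surface obeys

    dR/dt = kon * C * (Rmax - R) - koff * R

where ``R`` is the response (RU), ``C`` the analyte concentration (M), and
``kon`` / ``koff`` the association / dissociation rate constants.  With a
constant analyte concentration during the injection the ODE has the familiar
closed-form solution

    association:   R(t) = Req * (1 - exp(-kobs * (t - t0)))
                   kobs = kon * C + koff,   Req = Rmax * C / (C + Kd)
    dissociation:  R(t) = R0 * exp(-koff * (t - t0))

with Kd = koff / kon.  Both the closed form and a numerical ODE integration
are provided; the ODE path serves as an independent oracle for the closed
form in the test suite.

Mass-transport limitation, bulk refractive-index jumps and baseline drift
are deliberately not modelled: the fitting layer assumes a plain 1:1 model,
and each association phase starts from R = 0 (complete regeneration
between injection cycles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and surface capacity for a 1:1 interaction.

    Parameters
    ----------
    kon : float
        Association rate constant, M^-1 s^-1. Must be positive.
    koff : float
        Dissociation rate constant, s^-1. Must be positive.
    rmax : float
        Maximal analyte binding response, RU. Must be positive.
    temperature : float
        Temperature at which the constants apply, K.
    """

    kon: float
    koff: float
    rmax: float
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not (self.kon > 0 and self.koff > 0 and self.rmax > 0):
            raise ValueError(
                f"kon, koff and rmax must be positive, got "
                f"kon={self.kon}, koff={self.koff}, rmax={self.rmax}"
            )
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive (K), got {self.temperature}")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant koff/kon, M."""
        return self.koff / self.kon

    def req(self, concentration: float) -> float:
        """Equilibrium response Rmax*C/(C+Kd) at analyte concentration C (M)."""
        if concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {concentration}")
        if concentration == 0:
            return 0.0
        return self.rmax * concentration / (concentration + self.kd)

    def kobs(self, concentration: float) -> float:
        """Observed association-phase rate kon*C + koff, s^-1."""
        if concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {concentration}")
        return self.kon * concentration + self.koff


@dataclass(frozen=True)
class InjectionProtocol:
    """Timing of one injection cycle.

    The analyte flows over the surface from ``t_assoc_start`` to
    ``t_assoc_end`` (association phase); buffer flows until ``t_end``
    (dissociation phase).
    """

    t_assoc_start: float
    t_assoc_end: float
    t_end: float
    concentration: float
    sample_interval: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.t_assoc_start < self.t_assoc_end < self.t_end):
            raise ValueError(
                "require 0 <= t_assoc_start < t_assoc_end < t_end, got "
                f"({self.t_assoc_start}, {self.t_assoc_end}, {self.t_end})"
            )
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")
        if not self.sample_interval > 0:
            raise ValueError(f"sample_interval must be > 0, got {self.sample_interval}")

    def time_grid(self) -> np.ndarray:
        """Regular sampling grid covering the whole cycle."""
        n = int(round((self.t_end - self.t_assoc_start) / self.sample_interval))
        return self.t_assoc_start + self.sample_interval * np.arange(n + 1)


@dataclass
class SensorgramTrace:
    """One injection cycle's response time series with its metadata."""

    times: np.ndarray
    responses: np.ndarray
    concentration: float
    temperature: float
    t_assoc_start: float = 0.0
    t_assoc_end: float = np.inf
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.times.shape != self.responses.shape or self.times.size < 2:
            raise ValueError("times and responses must be equal-length arrays of size >= 2")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive (K), got {self.temperature}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, SensorgramTrace):
            return NotImplemented
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.responses, other.responses)
            and self.concentration == other.concentration
            and self.temperature == other.temperature
            and self.t_assoc_start == other.t_assoc_start
            and self.t_assoc_end == other.t_assoc_end
        )


def simulate_association(
    params: KineticParams, protocol: InjectionProtocol, t: np.ndarray
) -> np.ndarray:
    """Closed-form association-phase response on time grid ``t``.

    ``t`` is absolute time; the response is zero at ``protocol.t_assoc_start``
    and rises towards Req = Rmax*C/(C+Kd) with rate kobs = kon*C + koff.
    """
    t = np.asarray(t, dtype=float)
    c = protocol.concentration
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    req = params.req(c)
    kobs = params.kobs(c)
    return req * -np.expm1(-kobs * (t - protocol.t_assoc_start))


def simulate_dissociation(params: KineticParams, r0: float, t: np.ndarray) -> np.ndarray:
    """Closed-form dissociation decay R0*exp(-koff*t) on grid ``t``.

    ``t`` is time elapsed since the end of the injection (t=0 at the phase
    boundary, where the response equals ``r0``).
    """
    if r0 < 0:
        raise ValueError(f"r0 must be >= 0, got {r0}")
    t = np.asarray(t, dtype=float)
    return r0 * np.exp(-params.koff * t)


def simulate_clean(
    params: KineticParams, protocol: InjectionProtocol, t: np.ndarray
) -> np.ndarray:
    """Noise-free full-cycle response (association then dissociation)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    assoc = t <= protocol.t_assoc_end
    out[assoc] = simulate_association(params, protocol, t[assoc])
    r_end = simulate_association(params, protocol, np.array([protocol.t_assoc_end]))[0]
    dissoc = ~assoc
    out[dissoc] = simulate_dissociation(params, r_end, t[dissoc] - protocol.t_assoc_end)
    return out


def simulate_sensorgram(
    params: KineticParams,
    protocol: InjectionProtocol,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    t: np.ndarray | None = None,
    label: str = "",
) -> SensorgramTrace:
    """Simulate one injection cycle, optionally with Gaussian RU noise.

    Noise is i.i.d. homoscedastic Gaussian in response units, the simplest
    model consistent with Biacore residual behaviour.  ``seed`` may be an
    integer or a ``numpy.random.Generator``; a fixed integer seed makes the
    trace reproducible.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if t is None:
        t = protocol.time_grid()
    t = np.asarray(t, dtype=float)
    responses = simulate_clean(params, protocol, t)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        responses = responses + rng.normal(0.0, noise_sd, size=t.shape)
    return SensorgramTrace(
        times=t,
        responses=responses,
        concentration=protocol.concentration,
        temperature=params.temperature,
        t_assoc_start=protocol.t_assoc_start,
        t_assoc_end=protocol.t_assoc_end,
        label=label,
    )


def simulate_ode(
    params: KineticParams, protocol: InjectionProtocol, t: np.ndarray
) -> np.ndarray:
    """Numerically integrate dR/dt = kon*C*(Rmax-R) - koff*R over a cycle.

    Brute-force oracle for the closed-form solution; the analyte
    concentration is ``protocol.concentration`` during the association phase
    and zero afterwards.
    """
    t = np.asarray(t, dtype=float)

    def rhs(tt: float, r: np.ndarray) -> np.ndarray:
        c = protocol.concentration if tt <= protocol.t_assoc_end else 0.0
        return params.kon * c * (params.rmax - r) - params.koff * r

    out = np.zeros_like(t)
    assoc_mask = t <= protocol.t_assoc_end
    # integrate the two phases separately so the solver never steps across
    # the concentration discontinuity
    t_assoc = t[assoc_mask]
    r_bound = 0.0
    if t_assoc.size:
        sol = solve_ivp(
            rhs,
            (protocol.t_assoc_start, protocol.t_assoc_end),
            [0.0],
            t_eval=t_assoc,
            rtol=1e-12,
            atol=1e-12 * params.rmax,
            method="LSODA",
        )
        out[assoc_mask] = sol.y[0]
    sol_end = solve_ivp(
        rhs,
        (protocol.t_assoc_start, protocol.t_assoc_end),
        [0.0],
        rtol=1e-12,
        atol=1e-12 * params.rmax,
        method="LSODA",
    )
    r_bound = sol_end.y[0, -1]
    t_dissoc = t[~assoc_mask]
    if t_dissoc.size:
        sol = solve_ivp(
            rhs,
            (protocol.t_assoc_end, t_dissoc[-1]),
            [r_bound],
            t_eval=t_dissoc,
            rtol=1e-12,
            atol=1e-12 * params.rmax,
            method="LSODA",
        )
        out[~assoc_mask] = sol.y[0]
    return out
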
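"""Lumped two-compartment equivalent circuit of a cardiomyocyte and its
closed-form voltage-clamp step response.

The cell is represented by a surface membrane (capacitance ``C_s``, resistance
``R_ms``, reversal voltage ``U_ms``) in parallel with a tubular membrane
(``C_t``, ``R_mt``, ``U_mt``) that is coupled to the bath only through the
resistance of the tubule lumens ``R_t``; the whole cell is clamped through the
access resistance ``R_a``.  In low-conductivity (sucrose) extracellular
solution ``R_t`` is large and the capacitive current in response to a small
voltage step splits into two distinguishable exponential components, which is
what makes the separate determination of ``C_s`` and ``C_t`` possible.

All quantities use a self-consistent unit system: mV, MOhm, pF, nA and µs
(mV/MOhm = nA and MOhm·pF = µs), except that protocol durations and trace
time axes are expressed in ms at the API boundary.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CircuitParams",
    "DerivedCoeffs",
    "StepProtocol",
    "AnalyticStepResponse",
    "VERIFICATION_CIRCUIT",
    "derive_coeffs",
    "characteristic_time_constants",
    "steady_state",
    "steady_current",
    "analytic_step_response",
]

#: Relative tau_1/tau_2 separation below which the two exponential components
#: are treated as numerically indistinguishable.
DEGENERATE_TAU_RATIO = 1.0 + 1e-9

MS_TO_US = 1e3


@dataclass(frozen=True)
class CircuitParams:
    """The eight elements of the equivalent circuit.

    Parameters
    ----------
    R_a : float
        Access (pipette + bath path) resistance [MOhm].
    R_t : float
        Resistance of the tubular lumens [MOhm].
    R_ms, R_mt : float
        Surface / tubular membrane resistance [MOhm].
    C_s, C_t : float
        Surface / tubular membrane capacitance [pF].
    U_ms, U_mt : float
        Surface / tubular reversal voltage [mV].
    """

    R_a: float
    R_t: float
    R_ms: float
    R_mt: float
    C_s: float
    C_t: float
    U_ms: float = -160.0
    U_mt: float = -160.0

    def __post_init__(self) -> None:
        for name in ("R_a", "R_t", "R_ms", "R_mt", "C_s", "C_t"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(
                    f"circuit element {name} must be strictly positive and "
                    f"finite, got {value!r}"
                )
        for name in ("U_ms", "U_mt"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"reversal voltage {name} must be finite")

    # -- derived descriptive quantities ------------------------------------
    @property
    def k(self) -> float:
        """Capacitance ratio C_t/C_s (equals the membrane-area ratio)."""
        return self.C_t / self.C_s

    @property
    def C_m(self) -> float:
        """Total membrane capacitance C_s + C_t [pF]."""
        return self.C_s + self.C_t

    @property
    def f_t(self) -> float:
        """Tubular capacitance fraction C_t/(C_s + C_t)."""
        return self.C_t / (self.C_s + self.C_t)

    @property
    def gamma(self) -> float:
        """Proportionality coefficient between the conductance ratio
        G_mt/G_ms and the capacitance ratio C_t/C_s implied by the elements:
        gamma = (R_ms/R_mt)·(C_s/C_t)."""
        return (self.R_ms / self.R_mt) * (self.C_s / self.C_t)

    def replace(self, **changes: float) -> "CircuitParams":
        return dataclasses.replace(self, **changes)

    def with_tied_R_mt(self, gamma: float) -> "CircuitParams":
        """Return a copy with R_mt = (R_ms/gamma)·(C_s/C_t), i.e. with the
        conductance-capacitance proportionality enforced at the given gamma."""
        if gamma <= 0:
            raise ValueError("gamma must be positive")
        return self.replace(R_mt=(self.R_ms / gamma) * (self.C_s / self.C_t))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: Published verification values of the equivalent-circuit elements.
VERIFICATION_CIRCUIT = CircuitParams(
    R_a=12.5, R_t=15.0, R_ms=150.0, R_mt=241.0,
    C_s=74.0, C_t=46.0, U_ms=-160.0, U_mt=-160.0,
)


@dataclass(frozen=True)
class DerivedCoeffs:
    """Coefficients of the two-state ODE system.

    tau_t = R_t·C_t and tau_s = R_a·C_s [µs]; k_t = 1 + R_t/R_mt,
    k_st = 1 + R_a/R_ms + R_a/R_t and k_at = R_a/R_t [–];
    k_Ut = U_mt·R_t/R_mt and k_Us = U_ms·R_a/R_ms [mV].
    """

    tau_t: float
    tau_s: float
    k_t: float
    k_st: float
    k_at: float
    k_Ut: float
    k_Us: float

    @property
    def denom(self) -> float:
        """k_st·k_t − k_at, the common denominator of the steady state."""
        return self.k_st * self.k_t - self.k_at

    @property
    def degenerate(self) -> bool:
        """True when the tubular compartment collapses (tau_t -> 0)."""
        return (
            self.tau_t <= 0
            or not math.isfinite(self.k_at)
            or not math.isfinite(self.k_st)
        )


@dataclass(frozen=True)
class StepProtocol:
    """A single rectangular voltage step with optionally shaped edges.

    Times in ms; ``tau_p`` is the first-order time constant of the command
    edges (0 = ideal step).  The command is held at ``U_1`` for ``t_pre``
    before stepping to ``U_2`` for ``t_step``.
    """

    U_1: float = -80.0
    U_2: float = -75.0
    t_pre: float = 5.0
    t_step: float = 20.0
    tau_p: float = 0.05

    def __post_init__(self) -> None:
        if self.t_pre <= 0 or self.t_step <= 0:
            raise ValueError("durations t_pre and t_step must be positive")
        if self.tau_p < 0:
            raise ValueError("tau_p must be >= 0 (0 means an ideal step)")

    @property
    def delta_U(self) -> float:
        return self.U_2 - self.U_1


def derive_coeffs(params: CircuitParams) -> DerivedCoeffs:
    """Map the circuit elements to the ODE coefficients.

    Unit contract: MOhm·pF = µs and mV·(dimensionless) = mV.
    """
    return DerivedCoeffs(
        tau_t=params.R_t * params.C_t,
        tau_s=params.R_a * params.C_s,
        k_t=1.0 + params.R_t / params.R_mt,
        k_st=1.0 + params.R_a / params.R_ms + params.R_a / params.R_t,
        k_at=params.R_a / params.R_t,
        k_Ut=params.U_mt * params.R_t / params.R_mt,
        k_Us=params.U_ms * params.R_a / params.R_ms,
    )


def characteristic_time_constants(coeffs: DerivedCoeffs) -> tuple[float, float]:
    """The two time constants of the step response, tau_1 >= tau_2 [µs].

    The decay rates are the roots of

        lambda^2 − (k_t/tau_t + k_st/tau_s)·lambda
                 + (k_st·k_t − k_at)/(tau_s·tau_t) = 0,

    whose sum and product reproduce the characteristic-equation identities
    of the circuit.  Solved in the numerically stable form (larger root from
    the quadratic formula, smaller from the product).
    """
    if coeffs.degenerate:
        raise ValueError("degenerate coefficients: tau_t must be positive")
    rate_sum = coeffs.k_t / coeffs.tau_t + coeffs.k_st / coeffs.tau_s
    rate_prod = coeffs.denom / (coeffs.tau_s * coeffs.tau_t)
    disc = rate_sum * rate_sum - 4.0 * rate_prod
    if disc < 0:
        raise ValueError(
            "complex characteristic roots (discriminant < 0); the input does "
            "not correspond to a passive RC circuit"
        )
    rate_fast = 0.5 * (rate_sum + math.sqrt(disc))
    rate_slow = rate_prod / rate_fast
    return 1.0 / rate_slow, 1.0 / rate_fast


def steady_state(coeffs: DerivedCoeffs, U: float) -> tuple[float, float]:
    """Steady-state (U_s, U_t) [mV] under a constant command voltage U.

    Constants re-derived from the ODE system (the surface constant is
    (k_t·k_Us + k_at·k_Ut + k_t·U)/(k_st·k_t − k_at), the tubular one
    (k_Us + k_st·k_Ut + U)/(k_st·k_t − k_at)).
    """
    d = coeffs.denom
    U_s = (coeffs.k_t * coeffs.k_Us + coeffs.k_at * coeffs.k_Ut + coeffs.k_t * U) / d
    U_t = (coeffs.k_Us + coeffs.k_st * coeffs.k_Ut + U) / d
    return U_s, U_t


def steady_current(params: CircuitParams, U: float) -> float:
    """Steady membrane current J_inf = (U − U_s)/R_a [nA] at command U."""
    coeffs = derive_coeffs(params)
    U_s, _ = steady_state(coeffs, U)
    return (U - U_s) / params.R_a


@dataclass(frozen=True)
class AnalyticStepResponse:
    """Closed-form response to an ideal voltage step.

    ``t`` is in ms measured from the step onset; voltages in mV, currents in
    nA, time constants in µs.  ``J_1``/``J_2`` are the onset-referenced
    current amplitudes of the slow/fast components and ``J_inf_1``/``J_inf_2``
    the steady currents at the pre-/post-step voltage.
    """

    t: np.ndarray
    U_s: np.ndarray
    U_t: np.ndarray
    J: np.ndarray
    c_1: float
    c_2: float
    tau_1: float
    tau_2: float
    J_1: float
    J_2: float
    J_inf_1: float
    J_inf_2: float


def analytic_step_response(
    params: CircuitParams,
    protocol: StepProtocol,
    t: np.ndarray | None = None,
    dt: float = 0.01,
) -> AnalyticStepResponse:
    """Evaluate the closed-form step response on a time grid.

    Requires an ideal step (``protocol.tau_p == 0``); the initial condition is
    the steady state at ``U_1``.  ``t`` is in ms from the step onset and
    defaults to a uniform grid over the step duration.
    """
    if protocol.tau_p != 0:
        raise ValueError(
            "analytic_step_response requires an ideal step (tau_p = 0); "
            "use simulate_step for shaped edges"
        )
    coeffs = derive_coeffs(params)
    tau_1, tau_2 = characteristic_time_constants(coeffs)
    if tau_1 / tau_2 < DEGENERATE_TAU_RATIO:
        raise ValueError("components indistinguishable (tau_1 == tau_2)")
    if t is None:
        t = np.arange(0.0, protocol.t_step + dt / 2, dt)
    t = np.asarray(t, dtype=float)
    t_us = t * MS_TO_US

    U_1, U_2 = protocol.U_1, protocol.U_2
    d = coeffs.denom
    c_1 = (U_1 - U_2) / d * (tau_1 * coeffs.k_t - coeffs.tau_t) / (tau_1 - tau_2)
    c_2 = (U_1 - U_2) / d * (coeffs.tau_t - tau_2 * coeffs.k_t) / (tau_1 - tau_2)
    Us_inf, Ut_inf = steady_state(coeffs, U_2)

    e1 = np.exp(-t_us / tau_1)
    e2 = np.exp(-t_us / tau_2)
    U_s = c_1 * e1 + c_2 * e2 + Us_inf
    # tubular modal amplitudes follow from the eigenvector relation
    U_t = (
        c_1 / (coeffs.k_t - coeffs.tau_t / tau_1) * e1
        + c_2 / (coeffs.k_t - coeffs.tau_t / tau_2) * e2
        + Ut_inf
    )
    J = (U_2 - U_s) / params.R_a

    J_1 = -c_1 / params.R_a
    J_2 = -c_2 / params.R_a
    Us_inf_1, _ = steady_state(coeffs, U_1)
    J_inf_1 = (U_1 - Us_inf_1) / params.R_a
    J_inf_2 = (U_2 - Us_inf) / params.R_a
    return AnalyticStepResponse(
        t=t, U_s=U_s, U_t=U_t, J=J,
        c_1=c_1, c_2=c_2, tau_1=tau_1, tau_2=tau_2,
        J_1=J_1, J_2=J_2, J_inf_1=J_inf_1, J_inf_2=J_inf_2,
    )
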
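"""Bi-exponential decomposition of the capacitive transient.

The descending phase of the current response to a small voltage step is
fitted with

    J(t) = J_1 exp(−t/tau_1) + J_2 exp(−t/tau_2) + J_inf_2,

and, after supplementing the pre-step steady current J_inf_1, the six
parameters (J_1, J_2, J_inf_1, J_inf_2, tau_1, tau_2) fully determine the
recoverable elements of the equivalent circuit.  tau_1 always denotes the
longer time constant.

Two complications of real pulses are handled here:

* the command edge is not instantaneous but a first-order lag with time
  constant tau_p.  In a linear circuit this multiplies each decay mode's
  onset-referenced amplitude by exactly 1/(1 − tau_p/tau_i) and adds a third
  exponential mode at tau_p.  The default strategy (``edge_mode="model"``)
  includes that mode as an extra component with fixed tau_p, so the fitted
  model spans the exact response; ``edge_mode="exclude"`` instead starts the
  window late enough (default 12·tau_p) for the edge mode to have decayed.
* fitted amplitudes are referenced to the window start; they are reported
  back-extrapolated to the step onset and corrected by (1 − tau_p/tau_i), so
  they equal the ideal-step amplitudes and the extraction formulas apply
  literally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .circuit import MS_TO_US
from .simulate import CurrentTrace

__all__ = [
    "BiexpParams",
    "MonoexpParams",
    "BaselineEstimate",
    "FitDiagnostics",
    "extract_decay_window",
    "measure_baseline",
    "fit_biexponential",
    "fit_monoexponential",
    "fit_trace",
]

#: tau_1/tau_2 below this flags a mono-exponential (indistinguishable) fit.
INDISTINGUISHABLE_RATIO = 1.05

#: Default window delay, in multiples of tau_p, for edge_mode="exclude".
#: At 12 tau_p the edge mode has decayed to exp(-12) ~ 6e-6 of its amplitude.
DEFAULT_DELAY_MULT = 12.0

MIN_WINDOW_SAMPLES = 10


@dataclass
class FitDiagnostics:
    """Fit bookkeeping kept alongside the physical parameters."""

    rss: float
    n_points: int
    window_ms: tuple[float, float]
    origin_ms: float
    edge_mode: str
    raw_J_1: float
    raw_J_2: float
    edge_amplitude: float | None = None
    indistinguishable: bool = False
    message: str = ""
    covar: np.ndarray | None = None  # covariance of (J_1, J_2, tau_1, tau_2, J_inf_2)


@dataclass
class BiexpParams:
    """The six-parameter summary of a capacitive transient.

    Amplitudes in nA (onset-referenced, edge-corrected), time constants in
    µs with ``tau_1 >= tau_2``.  ``J_inf_1`` is the separately measured
    pre-step steady current.
    """

    J_1: float
    J_2: float
    tau_1: float
    tau_2: float
    J_inf_2: float
    J_inf_1: float | None = None
    diagnostics: FitDiagnostics | None = None

    def __post_init__(self) -> None:
        if self.tau_1 < self.tau_2:
            raise ValueError("tau_1 must be the longer time constant")
        if self.tau_2 <= 0:
            raise ValueError("time constants must be positive")

    def to_dict(self) -> dict:
        d = {
            "J_1": self.J_1, "J_2": self.J_2,
            "tau_1": self.tau_1, "tau_2": self.tau_2,
            "J_inf_2": self.J_inf_2, "J_inf_1": self.J_inf_1,
        }
        if self.diagnostics is not None:
            d["diagnostics"] = {
                "rss": self.diagnostics.rss,
                "n_points": self.diagnostics.n_points,
                "window_ms": list(self.diagnostics.window_ms),
                "origin_ms": self.diagnostics.origin_ms,
                "edge_mode": self.diagnostics.edge_mode,
                "raw_J_1": self.diagnostics.raw_J_1,
                "raw_J_2": self.diagnostics.raw_J_2,
                "edge_amplitude": self.diagnostics.edge_amplitude,
                "indistinguishable": self.diagnostics.indistinguishable,
                "message": self.diagnostics.message,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BiexpParams":
        diag = None
        if "diagnostics" in d and d["diagnostics"] is not None:
            dd = d["diagnostics"]
            diag = FitDiagnostics(
                rss=dd.get("rss", float("nan")),
                n_points=dd.get("n_points", 0),
                window_ms=tuple(dd.get("window_ms", (0.0, 0.0))),
                origin_ms=dd.get("origin_ms", 0.0),
                edge_mode=dd.get("edge_mode", ""),
                raw_J_1=dd.get("raw_J_1", float("nan")),
                raw_J_2=dd.get("raw_J_2", float("nan")),
                edge_amplitude=dd.get("edge_amplitude"),
                indistinguishable=dd.get("indistinguishable", False),
                message=dd.get("message", ""),
            )
        return cls(
            J_1=d["J_1"], J_2=d["J_2"], tau_1=d["tau_1"], tau_2=d["tau_2"],
            J_inf_2=d["J_inf_2"], J_inf_1=d.get("J_inf_1"), diagnostics=diag,
        )


@dataclass
class MonoexpParams:
    """Mono-exponential summary (physiological-solution regime).

    ``C_total`` estimates the whole-cell capacitance from the transferred
    capacitive charge Q = J_amp·tau divided by the voltage step, corrected
    for the voltage divider formed by the access and membrane resistance
    (exact for a single-compartment RC cell).
    """

    J_amp: float
    tau: float
    J_inf_2: float
    C_total: float | None = None
    diagnostics: FitDiagnostics | None = None


@dataclass
class BaselineEstimate:
    """Pre-step steady current J_inf_1 [nA] and its standard error."""

    value: float
    sem: float
    n: int


def _meta_default(trace: CurrentTrace, key: str, override, fallback):
    if override is not None:
        return override
    return trace.meta.get(key, fallback)


def measure_baseline(
    trace: CurrentTrace,
    onset_ms: float | None = None,
    window_ms: float = 5.0,
) -> BaselineEstimate:
    """Mean pre-step current over a tail window ending at the step onset."""
    onset = _meta_default(trace, "onset_ms", onset_ms, 0.0)
    mask = (trace.t < onset) & (trace.t >= onset - window_ms)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("trace has no pre-step samples before the onset")
    seg = trace.J[mask]
    sem = float(seg.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return BaselineEstimate(value=float(seg.mean()), sem=sem, n=n)


def extract_decay_window(
    trace: CurrentTrace,
    onset_ms: float | None = None,
    delay_ms: float | None = None,
    tau_p_ms: float | None = None,
    delay_mult: float = DEFAULT_DELAY_MULT,
    end_ms: float | None = None,
) -> CurrentTrace:
    """Cut the descending phase of the capacitive transient.

    The window starts at max(time of peak current, onset + delay) — with
    delay defaulting to ``delay_mult · tau_p`` — and ends at the pulse end
    (``end_ms`` or the end of the trace).  The window bounds are recorded in
    the sub-trace ``meta``.
    """
    onset = _meta_default(trace, "onset_ms", onset_ms, 0.0)
    tau_p = _meta_default(trace, "tau_p_ms", tau_p_ms, 0.0)
    if delay_ms is None:
        delay_ms = delay_mult * tau_p
    if end_ms is None and "t_step_ms" in trace.meta:
        end_ms = onset + trace.meta["t_step_ms"]

    step_mask = trace.t >= onset
    if not step_mask.any():
        raise ValueError("trace contains no samples after the step onset")
    t_step = trace.t[step_mask]
    J_step = trace.J[step_mask]

    pre = trace.J[trace.t < onset]
    ref = float(np.median(pre)) if len(pre) else float(J_step[-1])
    noise = float(pre.std(ddof=1)) if len(pre) > 2 else 0.0
    dev = np.abs(J_step - ref)
    i_pk = int(np.argmax(dev))
    if dev[i_pk] <= max(20.0 * noise, 1e-9):
        raise ValueError("no capacitive transient detected in the trace")

    t_start = max(t_step[i_pk], onset + delay_ms)
    window = trace.window(t_start, end_ms)
    if len(window) < MIN_WINDOW_SAMPLES:
        raise ValueError(
            f"decay window has {len(window)} samples "
            f"(< {MIN_WINDOW_SAMPLES}); trace too short or delay too long"
        )
    window.meta.update({
        "window_ms": (float(t_start), float(window.t[-1])),
        "onset_ms": onset,
        "tau_p_ms": tau_p,
    })
    return window


def _vp_solve(t_us, J, taus, edge=None):
    """Linear amplitudes for fixed time constants (variable projection)."""
    cols = [np.exp(-t_us / tau) for tau in taus] + [np.ones_like(t_us)]
    if edge is not None:
        cols.append(edge)
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, J, rcond=None)
    rss = float(((X @ coef - J) ** 2).sum())
    return coef, rss


def _vp_grid_init(t_us, J, n_components, edge=None, n_grid=20, init_taus=None):
    """Deterministic initial guess: scan a geometric grid of time-constant
    tuples, solving amplitudes linearly, and keep the best residual."""
    dt_us = t_us[1] - t_us[0]
    span = t_us[-1] - t_us[0]
    if init_taus is not None:
        taus = sorted(init_taus, reverse=True)[:n_components]
        coef, _ = _vp_solve(t_us, J, taus, edge)
        return list(taus), coef
    grid = np.geomspace(2 * dt_us, span, n_grid)
    best = None
    if n_components == 1:
        for tau in grid:
            coef, rss = _vp_solve(t_us, J, [tau], edge)
            if best is None or rss < best[0]:
                best = (rss, [tau], coef)
    else:
        for i in range(len(grid)):
            for j in range(i + 1, len(grid)):
                coef, rss = _vp_solve(t_us, J, [grid[j], grid[i]], edge)
                if best is None or rss < best[0]:
                    best = (rss, [grid[j], grid[i]], coef)
    return best[1], best[2]


def _report_covar(result, order, transform):
    """Covariance of the reported quantities via the delta method."""
    if result.covar is None:
        return None
    names = [p for p in result.params if result.params[p].vary]
    x0 = np.array([result.params[n].value for n in names])
    # numerical jacobian of transform(x) (reported vector) wrt fit params
    f0 = transform(dict(zip(names, x0)))
    G = np.empty((len(f0), len(x0)))
    for j, n in enumerate(names):
        h = 1e-7 * max(abs(x0[j]), 1e-6)
        xp = x0.copy(); xp[j] += h
        xm = x0.copy(); xm[j] -= h
        fp = transform(dict(zip(names, xp)))
        fm = transform(dict(zip(names, xm)))
        G[:, j] = (fp - fm) / (2 * h)
    return G @ result.covar @ G.T


def _exp_model(t_us, pars, edge, n_components):
    out = np.full_like(t_us, pars["off"])
    for i in range(1, n_components + 1):
        out = out + pars[f"a{i}"] * np.exp(-t_us / pars[f"tau{i}"])
    if edge is not None:
        out = out + pars["a_edge"] * edge
    return out


def _fit_exponentials(
    window: CurrentTrace,
    n_components: int,
    onset_ms: float,
    tau_p_ms: float,
    edge_mode: str,
    init_taus=None,
    max_tau_factor: float = 10.0,
):
    """Shared machinery for the mono- and bi-exponential fits."""
    t_us = (window.t - window.t[0]) * MS_TO_US
    J = window.J
    dt_us = t_us[1] - t_us[0]
    span = t_us[-1] - t_us[0]
    tau_p_us = tau_p_ms * MS_TO_US

    if edge_mode == "auto":
        edge_mode = "model" if tau_p_us > 0 else "none"
    edge = np.exp(-t_us / tau_p_us) if (edge_mode == "model" and tau_p_us > 0) else None

    init_t, init_coef = _vp_grid_init(
        t_us, J, n_components, edge, init_taus=init_taus)

    pars = lmfit.Parameters()
    for i, tau in enumerate(init_t, start=1):
        tau = min(max(tau, dt_us), max_tau_factor * span)
        pars.add(f"tau{i}", value=tau, min=dt_us, max=max_tau_factor * span)
        pars.add(f"a{i}", value=init_coef[i - 1])
    pars.add("off", value=init_coef[n_components])
    if edge is not None:
        pars.add("a_edge", value=init_coef[n_components + 1])

    def residual(p):
        vals = {k: p[k].value for k in p}
        return _exp_model(t_us, vals, edge, n_components) - J

    result = lmfit.minimize(
        residual, pars, method="leastsq", xtol=1e-14, ftol=1e-14,
        max_nfev=20000)
    if not result.success:
        raise RuntimeError(f"exponential fit did not converge: {result.message}")
    rss = float((result.residual ** 2).sum())

    shift_us = window.t[0] * MS_TO_US - onset_ms * MS_TO_US

    def reported(vals: dict) -> np.ndarray:
        """Onset-referenced, lag-corrected amplitudes + taus + offset."""
        out = []
        comps = sorted(
            range(1, n_components + 1),
            key=lambda i: -vals[f"tau{i}"],
        )
        for i in comps:
            tau = vals[f"tau{i}"]
            amp = vals[f"a{i}"] * math.exp(shift_us / tau)
            if tau_p_us > 0 and tau > tau_p_us:
                amp *= 1.0 - tau_p_us / tau
            out.append(amp)
        out.extend(vals[f"tau{i}"] for i in comps)
        out.append(vals["off"])
        return np.array(out)

    vals = {k: result.params[k].value for k in result.params}
    rep = reported(vals)
    covar = _report_covar(result, None, reported)
    return rep, vals, rss, edge_mode, covar, result


def fit_biexponential(
    window: CurrentTrace,
    onset_ms: float | None = None,
    tau_p_ms: float | None = None,
    edge_mode: str = "auto",
    init_taus: tuple[float, float] | None = None,
    max_tau_factor: float = 10.0,
) -> BiexpParams:
    """Least-squares bi-exponential fit of a pre-cut decay window.

    Returns onset-referenced, edge-corrected amplitudes (so they equal the
    ideal-step amplitudes of the closed-form response) with ``tau_1`` the
    longer constant.  A tau ratio below 1.05 raises no error but sets the
    ``indistinguishable`` diagnostic flag (mono-exponential regime, as in
    physiological solution).
    """
    onset = _meta_default(window, "onset_ms", onset_ms, 0.0)
    tau_p = _meta_default(window, "tau_p_ms", tau_p_ms, 0.0)
    rep, vals, rss, mode, covar, _ = _fit_exponentials(
        window, 2, onset, tau_p, edge_mode, init_taus, max_tau_factor)
    J_1, J_2, tau_1, tau_2, off = rep
    raw = sorted(
        [(vals["tau1"], vals["a1"]), (vals["tau2"], vals["a2"])], reverse=True)
    diag = FitDiagnostics(
        rss=rss,
        n_points=len(window),
        window_ms=tuple(window.meta.get("window_ms",
                                        (float(window.t[0]), float(window.t[-1])))),
        origin_ms=onset,
        edge_mode=mode,
        raw_J_1=raw[0][1],
        raw_J_2=raw[1][1],
        edge_amplitude=vals.get("a_edge"),
        indistinguishable=bool(tau_1 / tau_2 < INDISTINGUISHABLE_RATIO),
        covar=covar,
    )
    if diag.indistinguishable:
        diag.message = (
            "components indistinguishable (tau_1/tau_2 < "
            f"{INDISTINGUISHABLE_RATIO}); mono-exponential regime")
    return BiexpParams(
        J_1=float(J_1), J_2=float(J_2),
        tau_1=float(tau_1), tau_2=float(tau_2),
        J_inf_2=float(off), diagnostics=diag,
    )


def fit_monoexponential(
    window: CurrentTrace,
    onset_ms: float | None = None,
    tau_p_ms: float | None = None,
    edge_mode: str = "auto",
    U_1: float | None = None,
    U_2: float | None = None,
    J_inf_1: float | None = None,
) -> MonoexpParams:
    """Single-exponential fit plus a whole-cell capacitance estimate.

    ``C_total`` uses the transferred capacitive charge Q = J_amp·tau divided
    by the step amplitude, times the squared voltage-divider correction
    jump²/(J_amp·ΔU·…) — written as tau·jump²/(J_amp·ΔU) with
    jump = J_amp + (J_inf_2 − J_inf_1) — which is exact for a
    single-compartment cell behind an access resistance.
    """
    onset = _meta_default(window, "onset_ms", onset_ms, 0.0)
    tau_p = _meta_default(window, "tau_p_ms", tau_p_ms, 0.0)
    U_1 = _meta_default(window, "U_1", U_1, None)
    U_2 = _meta_default(window, "U_2", U_2, None)
    rep, vals, rss, mode, covar, _ = _fit_exponentials(
        window, 1, onset, tau_p, edge_mode)
    J_amp, tau, off = rep
    C_total = None
    if U_1 is not None and U_2 is not None and U_2 != U_1:
        dU = U_2 - U_1
        jump = J_amp + (off - J_inf_1 if J_inf_1 is not None else 0.0)
        C_total = float(tau * jump * jump / (J_amp * dU))
    diag = FitDiagnostics(
        rss=rss, n_points=len(window),
        window_ms=tuple(window.meta.get("window_ms",
                                        (float(window.t[0]), float(window.t[-1])))),
        origin_ms=onset, edge_mode=mode,
        raw_J_1=vals["a1"], raw_J_2=0.0,
        edge_amplitude=vals.get("a_edge"),
    )
    return MonoexpParams(
        J_amp=float(J_amp), tau=float(tau), J_inf_2=float(off),
        C_total=C_total, diagnostics=diag,
    )


def fit_trace(
    trace: CurrentTrace,
    onset_ms: float | None = None,
    tau_p_ms: float | None = None,
    edge_mode: str = "auto",
    delay_ms: float | None = None,
    delay_mult: float = DEFAULT_DELAY_MULT,
    baseline_window_ms: float = 5.0,
    end_ms: float | None = None,
    init_taus: tuple[float, float] | None = None,
) -> BiexpParams:
    """Baseline + window + bi-exponential fit of a full step/sweep trace.

    With ``edge_mode="model"`` (default when tau_p > 0) the window starts at
    the current peak and the edge mode is part of the model; with
    ``"exclude"`` the window starts at onset + delay_mult·tau_p instead.
    """
    onset = _meta_default(trace, "onset_ms", onset_ms, 0.0)
    tau_p = _meta_default(trace, "tau_p_ms", tau_p_ms, 0.0)
    mode = edge_mode
    if mode == "auto":
        mode = "model" if tau_p > 0 else "none"
    if delay_ms is None:
        delay_ms = 0.0 if mode == "model" else delay_mult * tau_p
    baseline = measure_baseline(trace, onset, baseline_window_ms)
    window = extract_decay_window(
        trace, onset, delay_ms=delay_ms, tau_p_ms=tau_p, end_ms=end_ms)
    params = fit_biexponential(
        window, onset, tau_p, edge_mode=mode, init_taus=init_taus)
    params.J_inf_1 = baseline.value
    if params.diagnostics is not None and baseline.sem > 0:
        # append baseline variance so downstream error propagation can use it
        params.diagnostics.message += (
            f" baseline sem = {baseline.sem:.3g} nA (n={baseline.n})")
    params.baseline = baseline  # type: ignore[attr-defined]
    return params
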
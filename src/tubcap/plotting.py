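"""Matplotlib helpers for traces, fits and γ-sensitivity sweeps."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_trace", "plot_fit", "plot_gamma_sweep"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_trace(trace, ax=None, **kwargs):
    """Current vs time; command voltage on a twin axis when available."""
    ax = _axes(ax)
    ax.plot(trace.t, trace.J, lw=0.8, **kwargs)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("current (nA)")
    if trace.U is not None:
        twin = ax.twinx()
        twin.plot(trace.t, trace.U, color="0.6", lw=0.8, ls="--")
        twin.set_ylabel("command (mV)")
    return ax


def plot_fit(results, ax=None):
    """Recorded trace with the fitted bi-exponential decomposition."""
    ax = _axes(ax)
    trace = results.model.trace
    ax.plot(trace.t, trace.J, lw=0.8, label="data", color="0.4")
    b = results.biexp
    w0, w1 = (b.diagnostics.window_ms if b.diagnostics is not None
              else (results.model.onset_ms, trace.t[-1]))
    t_fit = trace.t[(trace.t >= w0) & (trace.t <= w1)]
    ax.plot(t_fit, results.fitted_current(t_fit), lw=1.2, label="bi-exp fit")
    t_us = (t_fit - results.model.onset_ms) * 1e3
    for amp, tau, name in ((b.J_1, b.tau_1, "slow"), (b.J_2, b.tau_2, "fast")):
        ax.plot(t_fit, amp * np.exp(-t_us / tau) + b.J_inf_2, ls=":",
                label=f"{name} (tau = {tau:.0f} us)")
    ax.axvspan(w0, w1, color="0.92", zorder=0)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("current (nA)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_gamma_sweep(sweep, ax=None):
    """C_t and f_t error curves (or raw values) vs expected γ."""
    ax = _axes(ax)
    df = sweep.to_dataframe()
    if sweep.reference:
        for key, style in (("C_t", "-o"), ("f_t", "-s")):
            if key in sweep.reference:
                err = 100 * (df[key] / sweep.reference[key] - 1)
                ax.plot(df["gamma_expected"], err, style, ms=3, label=key)
        ax.axhline(0, color="0.7", lw=0.8)
        ax.set_ylabel("relative error (%)")
    else:
        ax.plot(df["gamma_expected"], df["C_t"], "-o", ms=3, label="C_t (pF)")
        ax.plot(df["gamma_expected"], 100 * df["f_t"], "-s", ms=3,
                label="f_t (%)")
        ax.set_ylabel("recovered value")
    ax.set_xlabel("expected gamma")
    ax.legend(frameon=False, fontsize=8)
    return ax
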
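"""Minimal diagnostic figures for traces and density sweeps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .time_course import CurrentTrace  # noqa: E402

__all__ = ["plot_trace", "plot_sweep"]


def plot_trace(trace: CurrentTrace, ax: plt.Axes | None = None,
               fit=None) -> plt.Axes:
    """Current versus time, optionally overlaying a mono-exponential fit."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.plot(trace.time, trace.current, lw=0.8, color="k", label="current")
    if fit is not None:
        t0 = trace.onset
        sel = trace.time >= t0
        import numpy as np

        model = fit.i_basal + fit.i_evoked * (
            1.0 - np.exp(-(trace.time[sel] - t0) / fit.tau_act)
        )
        ax.plot(trace.time[sel], model, color="crimson", lw=1.2,
                label=f"fit: tau = {fit.tau_act_ms:.0f} ms")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("current (uA)")
    return ax


def plot_sweep(table: pd.DataFrame, ax: plt.Axes | None = None) -> plt.Axes:
    """tau_act and I_evoked versus receptor density (log x), twin axes."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.semilogx(table.receptor_density, table.tau_act_ms, "o-", color="crimson")
    ax.set_xlabel("receptor density (molecules/um^2)")
    ax.set_ylabel("tau_act (ms)", color="crimson")
    twin = ax.twinx()
    twin.semilogx(table.receptor_density, table.i_evoked_uA, "s-", color="k")
    twin.set_ylabel("I_evoked (uA)")
    return ax
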
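"""Figure helpers: amplitude time courses, concentration-inhibition panels,
and EIP plots over the SDO/RFI/SSI axes."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .eip import EIPCurve, hill_inhibition, fit_hill

__all__ = [
    "plot_amplitude_timecourse",
    "plot_concentration_inhibition",
    "plot_eip_curves",
    "analysis_panel",
]


def plot_amplitude_timecourse(amplitudes: pd.DataFrame, pulses=(1, 7, 17), ax=None):
    """Per-pulse peak amplitudes vs experiment time."""
    if ax is None:
        _, ax = plt.subplots()
    for p in pulses:
        sel = amplitudes[amplitudes["pulse_index"] == p]
        ax.plot(sel["time_s"], sel["amplitude_nA"], ".", ms=3, label=f"#{p}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("peak current (nA)")
    ax.legend(title="pulse", fontsize="small")
    return ax


def plot_concentration_inhibition(ratio_table: pd.DataFrame, ax=None):
    """Per-pulse concentration-inhibition data with Hill fits."""
    if ax is None:
        _, ax = plt.subplots()
    cmap = plt.get_cmap("viridis")
    pulses = sorted(ratio_table["pulse_index"].unique())
    for i, p in enumerate(pulses):
        grp = ratio_table[ratio_table["pulse_index"] == p].sort_values("conc_uM")
        cc = grp["conc_uM"].to_numpy()
        inh = 1.0 - grp["ratio"].to_numpy()
        color = cmap(i / max(len(pulses) - 1, 1))
        ax.semilogx(cc, inh, "o-", ms=3, lw=1, color=color, alpha=0.7)
        try:
            fit = fit_hill(cc, inh, pulse_index=p)
            grid = np.geomspace(cc.min() / 3, cc.max() * 3, 100)
            ax.semilogx(grid, fit.predict(grid), "-", lw=0.5, color=color)
        except (ValueError, RuntimeError):
            pass
    ax.set_xlabel("concentration (µM)")
    ax.set_ylabel("inhibited fraction")
    ax.set_ylim(-0.05, 1.05)
    return ax


def plot_eip_curves(
    curves: Mapping[str, EIPCurve], axes: Optional[Sequence] = None
):
    """EIP (per-pulse IC50) vs conditioning duration / gap / holding level."""
    names = [s for s in ("SDO", "RFI", "SSI") if s in curves]
    if axes is None:
        _, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 3))
        if len(names) == 1:
            axes = [axes]
    for ax, name in zip(axes, names):
        c = curves[name]
        if name == "SSI":
            ax.semilogy(c.x, c.ic50, "o-")
            ax.set_xlabel("holding potential (mV)")
        else:
            ax.loglog(c.x, c.ic50, "o-")
            xlab = "conditioning duration (ms)" if name == "SDO" else \
                "interpulse gap (ms)"
            ax.set_xlabel(xlab)
        ax.set_ylabel("EIP: IC50 (µM)")
        ax.set_title(name)
    return axes


def analysis_panel(
    amplitudes: pd.DataFrame,
    ratio_table: pd.DataFrame,
    curves: Mapping[str, EIPCurve],
    figsize=(12, 7),
):
    """Amplitude plot, concentration-inhibition plot and the three EIP plots
    in one figure (the standard analysis-sequence layout)."""
    fig = plt.figure(figsize=figsize)
    gs = fig.add_gridspec(2, 3)
    plot_amplitude_timecourse(amplitudes, ax=fig.add_subplot(gs[0, 0:2]))
    plot_concentration_inhibition(ratio_table, ax=fig.add_subplot(gs[0, 2]))
    axes = [fig.add_subplot(gs[1, i]) for i in range(3)]
    plot_eip_curves(curves, axes=axes)
    fig.tight_layout()
    return fig
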
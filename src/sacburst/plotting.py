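"""Matplotlib convenience layer: trajectories, diagrams, heat maps.

These helpers style figures the way the bursting analysis is usually
presented (voltage/calcium stacked traces, V-vs-current branch diagrams,
log-scale interburst heat maps with silent cells blacked out). They are a
convenience only; nothing downstream depends on rendered output.
"""

from __future__ import annotations

import numpy as np

from .bifurcation import BifurcationDiagram1D
from .integrate import Trajectory

__all__ = ["plot_trajectory", "plot_bifurcation_diagram", "plot_ibi_heatmap"]


def plot_trajectory(traj: Trajectory, ax=None, calcium_threshold: float | None = 150.0):
    """Stacked membrane-potential and calcium traces against time (s)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    t_s = traj.times / 1000.0
    ax[0].plot(t_s, traj.V, lw=0.5, color="k")
    ax[0].set_ylabel("V (mV)")
    ax[1].plot(t_s, traj.C, lw=0.8, color="tab:blue")
    if calcium_threshold is not None:
        ax[1].axhline(calcium_threshold, color="tab:red", ls="--", lw=0.8)
    ax[1].set_ylabel("[Ca$^{2+}$] (nM)")
    ax[1].set_xlabel("time (s)")
    return ax


def plot_bifurcation_diagram(diag: BifurcationDiagram1D, ax=None):
    """Equilibrium branches (stable solid, unstable dotted) and cycle extremes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for I, fps in zip(diag.grid, diag.fixed_points):
        for fp in fps:
            ax.plot(I, fp.V_star, ".", ms=3,
                    color="tab:red" if fp.stable else "lightgray")
    cyc_I = [I for I, c in zip(diag.grid, diag.cycles) if c.exists]
    if cyc_I:
        ax.plot(cyc_I, [c.V_max for c in diag.cycles if c.exists], "g-", lw=1)
        ax.plot(cyc_I, [c.V_min for c in diag.cycles if c.exists], "g-", lw=1)
    for ev in diag.events:
        ax.axvline(ev.parameter_value, color="b", ls=":", lw=0.8)
        ax.annotate(ev.kind, (ev.parameter_value, ax.get_ylim()[1]),
                    rotation=90, fontsize=7, va="top")
    ax.set_xlabel(f"{diag.parameter} (pA)")
    ax.set_ylabel("V (mV)")
    return ax


def plot_ibi_heatmap(grid: np.ndarray, x_values, y_values, ax=None,
                     x_label="g_C (nS)", y_label="g_K (nS)"):
    """Log-scale mean-interburst heat map; silent cells rendered black."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    masked = np.ma.masked_invalid(np.asarray(grid, dtype=float) / 1000.0)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("black")
    im = ax.pcolormesh(x_values, y_values, masked, cmap=cmap,
                       norm=LogNorm() if masked.count() else None,
                       shading="nearest")
    ax.figure.colorbar(im, ax=ax, label=r"mean $\tau_{IBI}$ (s)")
    ax.set_xlabel(x_label)
    ax.set_ylabel(y_label)
    return ax
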
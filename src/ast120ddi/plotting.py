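"""Threshold-landscape and risk-scatter figures."""

from __future__ import annotations

import numpy as np

from .risk import DEFAULT_TH_RA, DEFAULT_TH_RD
from .thresholds import surface


def plot_threshold_surface(results, path, step: float = 1.0):
    """Contour map of the predictive value over (Rdth, Rath)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = np.arange(0.0, 100.0 + step / 2, step)
    z = surface(results, grid, grid)
    fig, ax = plt.subplots(figsize=(5, 4))
    cs = ax.contourf(grid, grid, z.T, levels=14, cmap="viridis")
    fig.colorbar(cs, ax=ax, label="predictive value (%)")
    ax.set_xlabel("Rd threshold (%)")
    ax.set_ylabel("Ra threshold (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_risk_scatter(
    assignments, path, th_rd: float = DEFAULT_TH_RD, th_ra: float = DEFAULT_TH_RA
):
    """(Rd, Ra) scatter per dosing interval with the quadrant lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    intervals = sorted({a.interval_min for a in assignments})
    n = len(intervals)
    fig, axes = plt.subplots(1, max(n, 1), figsize=(3.2 * max(n, 1), 3.2), squeeze=False)
    for ax, interval in zip(axes[0], intervals):
        pts = [a for a in assignments if a.interval_min == interval]
        ax.scatter([a.rd for a in pts], [a.ra for a in pts], s=18)
        ax.axvline(th_rd, color="grey", lw=0.8)
        ax.axhline(th_ra, color="grey", lw=0.8)
        ax.set_xlim(-3, 103)
        ax.set_ylim(-3, 103)
        ax.set_title(f"{interval} min")
        ax.set_xlabel("Rd (%)")
    axes[0][0].set_ylabel("Ra (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
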
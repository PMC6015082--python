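"""Rose (polar histogram) and averaged-profile plots.

Optional figure output for reports; all quantitative results live in
the CSV/JSON tables, these are views of them.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .circular import AngularDistribution

__all__ = ["rose_plot", "profile_plot"]


def rose_plot(
    dist: AngularDistribution,
    path: str | Path | None = None,
    title: str | None = None,
):
    """Polar histogram of the binned angular distribution.

    0 deg (the movement direction) points up; fractions are per 15-deg
    bin. Returns the figure; writes *path* when given.
    """
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    centers = np.radians(dist.bin_edges_deg[:-1] + dist.bin_width_deg / 2)
    ax.bar(centers, dist.bin_fractions, width=np.radians(dist.bin_width_deg),
           bottom=0.0, edgecolor="black", linewidth=0.5, alpha=0.8)
    ax.set_yticklabels([])
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def profile_plot(
    averaged: pd.DataFrame,
    path: str | Path | None = None,
    label: str = "Col1-3/4C",
):
    """Mean +/- SD averaged line-scan profile on the [-1, 1] cell axis."""
    fig, ax = plt.subplots(figsize=(5, 3))
    g = averaged["grid_coord"]
    ax.plot(g, averaged["mean"], lw=1.5, label=label)
    ax.fill_between(g, averaged["mean"] - averaged["sd"],
                    averaged["mean"] + averaged["sd"], alpha=0.3)
    ax.axvline(0.0, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("normalized cell axis (back = -1, nucleus = 0, front = 1)")
    ax.set_ylabel("max intensity (a.u.)")
    ax.legend(frameon=False)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
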
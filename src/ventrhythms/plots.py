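"""Figures: periodogram traces, heat maps, and the partition Venn."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .rhythm import PeriodogramResult
from .spatial import HeatMapGrid
from .varpart import VarpartResult

__all__ = ["plot_periodogram", "plot_heatmaps", "plot_varpart"]


def plot_periodogram(result: PeriodogramResult, title: str = "", path=None):
    """Amplitude vs candidate period; significant periods as black squares."""
    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.plot(result.periods, result.amplitude, color="0.6", lw=0.8, zorder=1)
    ax.scatter(
        result.periods[~result.significant],
        result.amplitude[~result.significant],
        marker="o", s=8, facecolors="none", edgecolors="0.4", zorder=2,
    )
    ax.scatter(
        result.periods[result.significant],
        result.amplitude[result.significant],
        marker="s", s=14, color="black", zorder=3,
        label=f"p < {result.alpha:g}",
    )
    ax.set_xlabel("Period (h)")
    ax.set_ylabel("WR amplitude (sd of column means)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_heatmaps(grid: HeatMapGrid, path=None):
    """One panel per taxon; linear colour scale, dark blue → dark red."""
    taxa = sorted(grid.counts)
    fig, axes = plt.subplots(1, len(taxa), figsize=(4 * len(taxa), 3.6),
                             squeeze=False)
    for ax, taxon in zip(axes[0], taxa):
        im = ax.imshow(grid.counts[taxon], cmap="jet", origin="upper",
                       interpolation="nearest")
        ax.set_title(taxon)
        fig.colorbar(im, ax=ax, shrink=0.8, label="observations")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_varpart(result: VarpartResult, labels=("X", "W"), path=None):
    """Two-set Venn of the adjusted-R² fractions [a], [b], [c], [d]."""
    from matplotlib.patches import Circle

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.add_patch(Circle((0.38, 0.5), 0.3, alpha=0.4, color="tab:orange"))
    ax.add_patch(Circle((0.62, 0.5), 0.3, alpha=0.4, color="tab:blue"))
    ax.text(0.25, 0.5, f"[a]\n{100 * result.a:.1f}%", ha="center", va="center")
    ax.text(0.5, 0.5, f"[b]\n{100 * result.b:.1f}%", ha="center", va="center")
    ax.text(0.75, 0.5, f"[c]\n{100 * result.c:.1f}%", ha="center", va="center")
    ax.text(0.5, 0.06, f"residuals [d] = {100 * result.d:.1f}%", ha="center")
    ax.text(0.2, 0.86, labels[0], ha="center", fontsize=12)
    ax.text(0.8, 0.86, labels[1], ha="center", fontsize=12)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.axis("off")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
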
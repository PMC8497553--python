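"""Minimal plotting helpers: LTT curves, disparity series, trait violins.

All functions take an optional matplotlib Axes and return it, so figures can
be composed; nothing here is required by the numerical pipeline.
"""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .ltt import LTTSeries
from .timeslice import SliceDistribution

__all__ = ["plot_ltt", "plot_series", "plot_violins"]


def plot_ltt(series: LTTSeries, ax=None, **kwargs):
    ax = ax or plt.gca()
    ax.step(series.ages, series.counts, where="post", **kwargs)
    ax.set_xlabel("age (Ma)")
    ax.set_ylabel("lineages")
    ax.invert_xaxis()
    return ax


def plot_series(series, column: str, ax=None, **kwargs):
    """One disparity/centroid column of a per-slice DataFrame against age."""
    ax = ax or plt.gca()
    ax.plot(series.index, series[column], **kwargs)
    ax.set_xlabel("age (Ma)")
    ax.set_ylabel(column)
    if not ax.xaxis_inverted():
        ax.invert_xaxis()
    return ax


def plot_violins(distributions: Sequence[SliceDistribution], ax=None, width: Optional[float] = None):
    """Violin plot of per-slice pooled trait distributions (KDE outlines)."""
    ax = ax or plt.gca()
    ages = [d.age for d in distributions]
    width = width or (0.4 * np.median(np.abs(np.diff(ages))) if len(ages) > 1 else 0.25)
    for d in distributions:
        if d.degenerate:
            ax.plot([d.age] * len(d.values), d.values, ".", color="gray", ms=2)
            continue
        dens = d.density / d.density.max() * width
        ax.fill_betweenx(d.grid, d.age - dens, d.age + dens, alpha=0.6, lw=0.3)
    ax.set_xlabel("age (Ma)")
    if not ax.xaxis_inverted():
        ax.invert_xaxis()
    return ax
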
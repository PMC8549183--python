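"""Quick-look figures for ordination and movement results.

Thin matplotlib wrappers; every function returns the Axes so callers can
restyle.  Nothing here is needed for the numerical pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends
import matplotlib.pyplot as plt  # noqa: E402

from .multivariate import OrdinationResult

__all__ = ["plot_ordination", "plot_displacement_trends"]


def plot_ordination(result: OrdinationResult, groups=None, ax=None,
                    axis_names: tuple[str, str] = ("axis 1", "axis 2")):
    """Scatter the first two ordination axes, coloured by group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    coords = result.coordinates
    if coords.shape[1] < 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
    if groups is None:
        ax.scatter(coords[:, 0], coords[:, 1], s=18)
    else:
        groups = pd.Series(groups).astype(str)
        for g in sorted(groups.unique()):
            sel = (groups == g).to_numpy()
            ax.scatter(coords[sel, 0], coords[sel, 1], s=18, label=g)
        ax.legend(frameon=False, fontsize=8)
    fr = result.axis_fractions
    ax.set_xlabel(f"{axis_names[0]} ({100 * fr[0]:.1f}%)" if len(fr) > 0 else axis_names[0])
    ax.set_ylabel(f"{axis_names[1]} ({100 * fr[1]:.1f}%)" if len(fr) > 1 else axis_names[1])
    return ax


def plot_displacement_trends(trends: pd.DataFrame, ax=None,
                             genotype_col: str = "genotype",
                             time_col: str = "time_s"):
    """Mean displacement and LOESS curve per genotype over time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for g, sub in trends.groupby(genotype_col):
        sub = sub.sort_values(time_col)
        ax.plot(sub[time_col], sub["loess"], label=g)
        ax.scatter(sub[time_col], sub["mean"], s=10, alpha=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("mean displacement (µm)")
    ax.legend(frameon=False, fontsize=8)
    return ax
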
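"""Plots of similarity curves and amplitude profiles (matplotlib)."""

from __future__ import annotations

import numpy as np

from .tuning import tuning_density

__all__ = ["plot_similarity_curves", "plot_psc_profile"]


def plot_similarity_curves(curves, fit=None, ax=None, title=None):
    """Similarity (classification-error) curves, one line per reference
    numerosity, with the fitted tuning model overlaid if given.

    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c in curves:
        ax.plot(c.probes, c.values, "o-", label=f"n = {c.reference_n}")
        if fit is not None:
            grid = np.linspace(min(c.probes), max(c.probes), 200)
            ax.plot(
                grid,
                fit.scale_hat * tuning_density(grid, c.reference_n, fit.w_hat),
                "--", color="gray", linewidth=0.8,
            )
    ax.set_xlabel("probe numerosity")
    ax.set_ylabel("classification error")
    if title:
        ax.set_title(title)
    ax.legend(fontsize="small")
    return ax


def plot_psc_profile(records, ax=None):
    """Mean percent signal change as a function of numerosity per
    arrangement, pooled over hemispheres and subjects; the vertical line
    marks the subitizing limit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    means = (
        records.groupby(["arrangement", "numerosity"], observed=True)["psc"]
        .mean()
        .reset_index()
    )
    for arr, grp in means.groupby("arrangement", observed=True):
        ax.plot(grp["numerosity"], grp["psc"], "o-", label=arr)
    ax.axvline(4.5, color="gray", linestyle=":", linewidth=1)
    ax.set_xlabel("numerosity")
    ax.set_ylabel("percent signal change")
    ax.legend()
    return ax
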
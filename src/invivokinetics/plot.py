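"""Minimal plotting: the saturation curve with data points and fit."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .fitting import FitResult, KineticDataset, michaelis_menten

__all__ = ["plot_saturation"]


def plot_saturation(
    data: KineticDataset,
    fit: Optional[FitResult] = None,
    path: str | Path | None = None,
    ax=None,
):
    """Scatter the (substrate, rate) pairs and overlay the fitted rate law.

    When the fit carries Monte-Carlo samples, a pointwise 95% band of the
    resampled curves is shaded.  Returns the matplotlib axes; saves to
    ``path`` if given.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(data.substrate, data.rate, "o", ms=5, alpha=0.8, label="replicates")
    if fit is not None:
        grid = np.geomspace(data.substrate.min(), data.substrate.max(), 200)
        ax.plot(grid, fit.predicted(grid), "r-", label="Michaelis-Menten fit")
        if fit.mc_samples is not None and fit.mc_samples["vmax"].size:
            curves = michaelis_menten(
                grid[None, :],
                fit.mc_samples["vmax"][:, None],
                fit.mc_samples["k_half"][:, None],
            )
            lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
            ax.fill_between(grid, lo, hi, color="r", alpha=0.2, lw=0, label="MC 95% band")
    ax.set_xlabel("substrate (µM)")
    ax.set_ylabel("rate (µM/h)")
    ax.set_xscale("log")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
    return ax
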
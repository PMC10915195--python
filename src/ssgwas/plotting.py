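"""Plots for window-variance profiles."""

from __future__ import annotations

import numpy as np


def plot_window_variances(table, trait: str, ax=None, threshold: float | None = None):
    """Manhattan-style plot of a window-variance table for one trait:
    percentage of additive variance per window along the genome, colored by
    chromosome, with an optional selection-threshold line."""
    import matplotlib.pyplot as plt

    sub = table.loc[table["trait"] == trait].reset_index(drop=True)
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    x0 = 0
    for i, (chrom, cs) in enumerate(sub.groupby("chrom", sort=False)):
        x = x0 + np.arange(len(cs))
        ax.scatter(x, cs["pct"], s=4, color=f"C{i % 10}", label=str(chrom))
        x0 += len(cs)
    if threshold is not None:
        ax.axhline(threshold, color="k", ls="--", lw=0.8)
    ax.set_xlabel("window (genome order)")
    ax.set_ylabel("% of additive variance")
    ax.set_title(trait)
    return ax
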
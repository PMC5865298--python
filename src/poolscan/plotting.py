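"""Convenience Manhattan-style plot of Z-transformed window statistics."""
from __future__ import annotations

import pandas as pd


def manhattan(table: pd.DataFrame, column: str, threshold: float = 6.0,
              direction: str = "lower", ax=None):
    """Plot one Z column of the window table along the genome.

    Chromosomes are laid out end to end in alternating colors with a dashed
    line at the outlier cut-off. Returns the matplotlib Axes.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    for i, (chrom, sub) in enumerate(table.groupby("chrom", sort=False)):
        x = (sub["start"] + sub["end"]) / 2 + offset
        ax.scatter(x, sub[column], s=4, color=("#1f77b4", "#ff7f0e")[i % 2],
                   label=None)
        offset += int(sub["end"].max())
    cut = -threshold if direction == "lower" else threshold
    ax.axhline(cut, linestyle="--", color="grey")
    ax.set_xlabel("genome position (chromosomes concatenated)")
    ax.set_ylabel(column)
    return ax
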
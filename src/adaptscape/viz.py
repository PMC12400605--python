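"""Minimal score plots (convenience only)."""

from __future__ import annotations

import pandas as pd


def manhattan(scores: pd.DataFrame, stat: str, threshold: float | None = None, ax=None):
    """Manhattan-style plot of a per-SNP statistic with cumulative coordinates."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    for i, (chrom, grp) in enumerate(scores.groupby("chrom", sort=False)):
        x = grp["pos"].to_numpy() + offset
        ax.scatter(x, grp[stat], s=2, color="C0" if i % 2 == 0 else "C1", rasterized=True)
        offset = x.max() + 1
    if threshold is not None:
        ax.axhline(threshold, ls=":", color="k")
    ax.set_xlabel("cumulative position (bp)")
    ax.set_ylabel(stat)
    return ax
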
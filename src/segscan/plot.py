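"""Optional Manhattan-style plot of a genome scan (convenience only)."""

from __future__ import annotations

import pandas as pd


def manhattan(scan_df: pd.DataFrame, ax=None, threshold: float | None = None):
    """Plot per-SNP log odds along concatenated chromosomes.

    Requires matplotlib (install the ``plot`` extra).  Returns the axes.
    """
    import matplotlib.pyplot as plt  # lazy: plotting is not a core dependency

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, sub) in enumerate(scan_df.groupby("chrom", sort=True)):
        x = sub["pos"].to_numpy() + offset
        ax.scatter(x, sub["log_odds"], s=6, color="C0" if i % 2 == 0 else "C1")
        ticks.append(offset + sub["pos"].mean())
        labels.append(str(chrom))
        offset += sub["pos"].max()
    if threshold is not None:
        ax.axhline(threshold, color="grey", ls="--", lw=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("log odds")
    return ax
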
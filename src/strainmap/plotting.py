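"""Basic plot helpers: Manhattan plot and module dendrogram."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from scipy.cluster.hierarchy import dendrogram  # noqa: E402

from .mixedmodel import AssociationResult  # noqa: E402
from .coexnet import CoexpressionNetwork  # noqa: E402


def manhattan_plot(assoc: AssociationResult, threshold: float = 5.39,
                   path=None):
    """-log10 P along the genome with alternating chromosome shading."""
    t = assoc.table.dropna(subset=["neglog10P"]).copy()
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, ticklabels = [], []
    for i, (chrom, sub) in enumerate(t.groupby("chrom", sort=True)):
        x = sub["pos"].to_numpy() + offset
        ax.scatter(x, sub["neglog10P"], s=4,
                   color="#1f4e8c" if i % 2 else "#7fa8d9")
        ticks.append(offset + sub["pos"].max() / 2)
        ticklabels.append(str(chrom))
        offset += sub["pos"].max()
    ax.axhline(threshold, color="red", lw=0.8, ls="--")
    ax.set_xticks(ticks)
    ax.set_xticklabels(ticklabels)
    ax.set_ylabel(r"$-\log_{10} P$")
    ax.set_title(assoc.trait)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def dendrogram_plot(network: CoexpressionNetwork, path=None):
    """Gene dendrogram with module color bar."""
    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(9, 4), height_ratios=[4, 1], sharex=False)
    dd = dendrogram(network.modules.dendrogram, no_labels=True, ax=ax0,
                    color_threshold=0)
    order = dd["leaves"]
    colors = np.asarray(network.labels)[order]
    ax1.bar(range(len(colors)), np.ones(len(colors)), width=1.0,
            color=[c if c != "grey" else "#cccccc" for c in colors])
    ax1.set_yticks([])
    ax1.set_xticks([])
    ax0.set_ylabel("1 - TOM merge height")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
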
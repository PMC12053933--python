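"""Cosmetic figures: volcano plot and NES bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["volcano_plot", "nes_barplot"]


def volcano_plot(results: pd.DataFrame, alpha: float = 0.05, path=None):
    """Volcano of log2 fold-change vs -log10 adjusted p.

    Tumor-overexpressed significant proteins are red, underexpressed blue,
    non-significant gray.
    """
    fig, ax = plt.subplots(figsize=(6, 5))
    q = results["q"].clip(lower=1e-300)
    sig = results["q"] < alpha
    up = sig & (results["log2_fc"] > 0)
    down = sig & (results["log2_fc"] < 0)
    ax.scatter(results.loc[~sig, "log2_fc"], -np.log10(q[~sig]), s=6, c="0.7")
    ax.scatter(results.loc[up, "log2_fc"], -np.log10(q[up]), s=6, c="tab:red")
    ax.scatter(results.loc[down, "log2_fc"], -np.log10(q[down]), s=6, c="tab:blue")
    ax.set_xlabel("log2 fold-change (tumor / adjacent)")
    ax.set_ylabel("-log10 adjusted p")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def nes_barplot(enrichment: pd.DataFrame, top: int = 20, path=None):
    """Horizontal bars of normalized enrichment scores for the top sets."""
    e = enrichment.sort_values("q").head(top).sort_values("nes")
    fig, ax = plt.subplots(figsize=(6, 0.3 * max(len(e), 4) + 1))
    colors = ["tab:red" if v > 0 else "tab:blue" for v in e["nes"]]
    ax.barh(e.index.astype(str), e["nes"], color=colors)
    ax.set_xlabel("NES")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
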
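"""Plots for study results: robustness/effect-size dot plots and proxy
correlation heatmaps."""

from __future__ import annotations

from typing import Sequence

import matplotlib
import numpy as np
import pandas as pd

__all__ = ["plot_robustness", "plot_proxy_correlations"]


def plot_robustness(summaries: pd.DataFrame, kind: str = "independent", ax=None):
    """Dot plot of mean significant R-squared increment per proxy.

    Proxies are ordered by effect size; the marker size scales with the
    fraction of brain-cognition models in which the effect replicated.
    """
    import matplotlib.pyplot as plt

    sub = summaries[summaries["kind"] == kind].copy()
    sub = sub.dropna(subset=["mean_delta_r2_significant"])
    sub = sub.sort_values("mean_delta_r2_significant")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, max(2, 0.28 * len(sub))))
    y = np.arange(len(sub))
    sizes = 20 + 80 * sub["robustness_pct"].to_numpy() / 100.0
    ax.scatter(sub["mean_delta_r2_significant"], y, s=sizes, color="k")
    ax.set_yticks(y)
    ax.set_yticklabels(sub["proxy"])
    ax.set_xlabel(r"mean significant $\Delta R^2$")
    ax.set_title(f"{kind} effects (marker size = replication robustness)")
    return ax


def plot_proxy_correlations(df: pd.DataFrame, proxy_names: Sequence[str], ax=None):
    """Heatmap of Pearson correlations between individual proxies."""
    import matplotlib.pyplot as plt

    corr = df[list(proxy_names)].corr()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(corr.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(proxy_names)))
    ax.set_xticklabels(proxy_names, rotation=45, ha="right")
    ax.set_yticks(range(len(proxy_names)))
    ax.set_yticklabels(proxy_names)
    for i in range(len(proxy_names)):
        for j in range(len(proxy_names)):
            ax.text(j, i, f"{corr.values[i, j]:.2f}", ha="center", va="center",
                    fontsize=7)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax
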
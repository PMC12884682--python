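"""Publication-style figures for classified populations.

Two standard views: a per-cell peri-event heatmap with cells sorted by
their time of peak normalized rate, and grouped bars of per-epoch
excited/inhibited/nonresponsive proportions.  Both write to file and
return the Matplotlib figure for further styling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def heatmap_sorted_by_peak(time_bins: np.ndarray, z: np.ndarray, path=None,
                           title: str = ""):
    """Cells × time heatmap of z-normalized rates, rows sorted by the
    time bin of each cell's peak."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(np.argmax(z, axis=1))
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(z[order], aspect="auto", interpolation="nearest",
                   extent=(time_bins[0], time_bins[-1], z.shape[0], 0),
                   cmap="viridis")
    ax.axvline(0.0, color="w", ls="--", lw=0.8)
    ax.set_xlabel("time from alignment event (s)")
    ax.set_ylabel("cell (sorted by peak time)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="z rate")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def proportion_bars(prop_table: pd.DataFrame, groups: list[str], path=None):
    """Grouped bars of excited/inhibited/nonresponsive shares per epoch."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    kinds = ["excited", "inhibited", "nonresponsive"]
    colors = {"excited": "forestgreen", "inhibited": "firebrick",
              "nonresponsive": "lightgray"}
    epochs = prop_table["epoch"].tolist()
    x = np.arange(len(epochs), dtype=float)
    width = 0.8 / len(groups)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for gi, g in enumerate(groups):
        totals = sum(prop_table[f"{k}_{g}"] for k in kinds).to_numpy(float)
        bottom = np.zeros(len(epochs))
        for k in kinds:
            frac = prop_table[f"{k}_{g}"].to_numpy(float) / totals
            ax.bar(x + gi * width, frac, width * 0.9, bottom=bottom,
                   color=colors[k], edgecolor="k", linewidth=0.3,
                   label=k if gi == 0 else None)
            bottom += frac
        ax.text(x[0] + gi * width, 1.02, g, rotation=45, fontsize=7,
                ha="left")
    ax.set_xticks(x + width * (len(groups) - 1) / 2)
    ax.set_xticklabels(epochs)
    ax.set_ylabel("fraction of cells")
    ax.set_xlabel("trial epoch")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
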
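"""Optional figures: concordance boxplots and CVA centroid plots."""
from __future__ import annotations

import numpy as np
import pandas as pd


def concordance_boxplot(table: pd.DataFrame, by: str, ax=None):
    """Boxplots of Mantel R grouped by a label column (measurer/species/method)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    groups = sorted(table[by].unique())
    data = [table.loc[table[by] == g, "R"].to_numpy() for g in groups]
    ax.boxplot(data, tick_labels=groups, whis=(0, 100))
    ax.set_ylabel("Mantel R")
    ax.set_xlabel(by)
    ax.set_ylim(-0.05, 1.05)
    return ax


def cva_centroid_plot(result, site_labels, measurer_labels, ax=None):
    """Group centroids (site x measurer) with min/max whiskers on CV1/CV2."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    scores = result.scores
    if scores.shape[1] < 2:
        scores = np.column_stack([scores[:, 0], np.zeros(len(scores))])
    colors = {m: c for m, c in zip(sorted(set(measurer_labels)),
                                   ["tab:red", "tab:green", "tab:blue",
                                    "tab:orange", "tab:purple"])}
    markers = {s: mk for s, mk in zip(sorted(set(site_labels)),
                                      ["^", "s", "o", "D", "v"])}
    for m in sorted(set(measurer_labels)):
        for s in sorted(set(site_labels)):
            mask = (np.asarray(measurer_labels) == m) & (np.asarray(site_labels) == s)
            if not mask.any():
                continue
            pts = scores[mask]
            cx, cy = pts[:, 0].mean(), pts[:, 1].mean()
            ax.plot([pts[:, 0].min(), pts[:, 0].max()], [cy, cy],
                    color=colors[m], lw=0.6, alpha=0.5)
            ax.plot([cx, cx], [pts[:, 1].min(), pts[:, 1].max()],
                    color=colors[m], lw=0.6, alpha=0.5)
            ax.scatter([cx], [cy], color=colors[m], marker=markers[s], s=60,
                       edgecolor="k", linewidth=0.4, zorder=3)
    pv = result.percent_variance
    ax.set_xlabel(f"CV1 ({pv[0]:.1f}%)" if len(pv) > 0 else "CV1")
    ax.set_ylabel(f"CV2 ({pv[1]:.1f}%)" if len(pv) > 1 else "CV2")
    return ax
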
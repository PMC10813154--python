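"""Simple diagnostic plots: per-comparison distributions and best-cell heatmap.

Deliberately plain matplotlib renderings — enough to inspect a run,
not publication styling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import FeatureMatrix


def plot_group_distributions(matrix: FeatureMatrix, column: str,
                             groups: list[str], ax=None):
    """Violin plot of one feature column split by diagnostic group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    labels = matrix.groups.astype(str)
    data = [matrix.data.loc[(labels == g).values, column].to_numpy()
            for g in groups]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(groups) + 1), groups)
    ax.set_ylabel(column)
    return ax


def plot_best_heatmap(best: pd.DataFrame, ax=None):
    """Heatmap of the best-cell metric table (rows=comparisons)."""
    import matplotlib.pyplot as plt

    metric_cols = [c for c in ("accuracy", "recall", "precision", "f1",
                               "auc", "kappa", "mcc", "csi", "gmean")
                   if c in best.columns]
    vals = best[metric_cols].astype(float).to_numpy()
    # scale the [0,1] metrics up so one colour map serves all columns
    scaled = vals.copy()
    for j, c in enumerate(metric_cols):
        if c in ("auc", "kappa", "mcc", "csi", "gmean"):
            scaled[:, j] = vals[:, j] * 100.0
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(best) + 1))
    im = ax.imshow(scaled, cmap="Greens", vmin=0, vmax=100, aspect="auto")
    ax.set_xticks(range(len(metric_cols)), metric_cols, rotation=45)
    ax.set_yticks(range(len(best)), best["comparison"])
    for i in range(scaled.shape[0]):
        for j in range(scaled.shape[1]):
            if np.isfinite(vals[i, j]):
                ax.text(j, i, f"{vals[i, j]:.2f}", ha="center", va="center",
                        fontsize=6)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax
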
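"""Optional thin plotting layer (not part of the tested core)."""

from __future__ import annotations

import numpy as np

from .relations import RelationFrequencyMatrix
from .simulate import spectral_grid


def plot_relation_heatmap(result: RelationFrequencyMatrix, ax=None, cmap="viridis"):
    """Cluster-ordered heatmap of relation detection frequencies."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    freq = result.frequencies
    ro = result.row_order if result.row_order is not None else np.arange(freq.shape[0])
    co = result.col_order if result.col_order is not None else np.arange(freq.shape[1])
    grid = spectral_grid().astype(int)
    img = ax.imshow(freq[np.ix_(ro, co)], vmin=0, vmax=1, cmap=cmap)
    ax.set_xticks(range(len(co)), [grid[result.targets[i]] for i in co], rotation=90)
    ax.set_yticks(range(len(ro)), [grid[result.targets[i]] for i in ro])
    ax.set_xlabel("related variable (cm$^{-1}$)")
    ax.set_ylabel("target variable (cm$^{-1}$)")
    ax.figure.colorbar(img, ax=ax, label="detection frequency")
    return ax


def plot_performance(metrics, ax=None):
    """Band sensitivity vs. false positive rate per method (one f value)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for method, sub in metrics.groupby("method"):
        ax.scatter(
            100 * sub["false_positive_rate"], sub["band_sensitivity"], label=method
        )
    ax.set_xlabel("false positive rate (%)")
    ax.set_ylabel("sensitivity of band identification")
    ax.set_ylim(0, 1.05)
    ax.legend()
    return ax
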
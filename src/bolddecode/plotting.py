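"""Optional figures: permutation-null histograms and confusion heatmaps.

Kept out of the core pipeline; requires matplotlib.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import PermutationResult


def plot_null_distribution(result: PermutationResult, ax=None, bins=30):
    """Histogram of the permutation null with the observed accuracy marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(result.null, bins=bins, color="0.7", edgecolor="0.4")
    ax.axvline(result.observed, color="red", linewidth=2)
    ax.set_xlabel("group-average accuracy")
    ax.set_ylabel("permutations")
    ax.set_title(f"observed {result.observed:.3f}  (p {result.p_report})")
    return ax


def plot_confusion(confusion: pd.DataFrame, ax=None, cmap="viridis"):
    """Heatmap of a guesses x targets confusion matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    m = confusion.to_numpy(dtype=float)
    im = ax.imshow(m, cmap=cmap)
    ax.set_xticks(range(m.shape[1]), labels=list(confusion.columns),
                  rotation=45, ha="right")
    ax.set_yticks(range(m.shape[0]), labels=list(confusion.index))
    ax.set_xlabel("target")
    ax.set_ylabel("guess")
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            ax.text(j, i, f"{m[i, j]:.3g}", ha="center", va="center",
                    color="white" if m[i, j] < np.nanmax(m) / 2 else "black")
    ax.figure.colorbar(im, ax=ax, label="guesses")
    return ax
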
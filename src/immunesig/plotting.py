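"""Minimal plots: consensus heatmaps and signature-profile heatmaps."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .consensus import ConsensusResult

__all__ = ["consensus_heatmap", "profile_heatmap"]


def _ordered(consensus: np.ndarray) -> np.ndarray:
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    order = leaves_list(average(squareform(dist, checks=False)))
    return consensus[np.ix_(order, order)]


def consensus_heatmap(result: ConsensusResult, path: str | Path) -> None:
    """Items ordered by the consensus dendrogram; white=0, saturated=1."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cmap = "Blues" if result.algorithm == "kmeans" else "Reds"
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(_ordered(result.consensus), cmap=cmap, vmin=0, vmax=1, interpolation="nearest")
    ax.set_title(f"{result.dataset} {result.algorithm} k={result.k}")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def profile_heatmap(profiles: pd.DataFrame, path: str | Path) -> None:
    """Signatures × reference groups heatmap of mean enrichment scores."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.45 * profiles.shape[1] + 2, 0.4 * profiles.shape[0] + 2))
    im = ax.imshow(profiles.to_numpy(), cmap="RdBu_r", aspect="auto")
    ax.set_xticks(range(profiles.shape[1]), profiles.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(profiles.shape[0]), profiles.index, fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
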
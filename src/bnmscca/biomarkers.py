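"""Rank ROIs by averaged canonical-weight magnitude and tabulate weights.

The top-ranked regions, annotated with their brain-network membership, are
the candidate biomarkers the association stage delivers; the heatmap table
lines up the averaged signed weights of several methods for comparison.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datamodel import GroupStructure
from .exceptions import ValidationError

__all__ = ["top_k", "weight_heatmap_table", "plot_weight_heatmap"]


def top_k(weights, labels, groups: GroupStructure | None = None, k: int = 10) -> pd.DataFrame:
    """Top-k features by |weight|, signed weights reported.

    Ties in magnitude are broken by feature-label lexicographic order.
    Returns a DataFrame with columns roi, network, weight, rank.
    """
    w = np.asarray(weights, dtype=float).ravel()
    labels = [str(x) for x in labels]
    if len(labels) != w.size:
        raise ValidationError("labels do not match the weight vector")
    if not (1 <= k <= w.size):
        raise ValidationError(f"k={k} outside 1..{w.size}")
    if not np.any(w):
        warnings.warn("all weights are zero: ranking is purely lexicographic")
    order = sorted(range(w.size), key=lambda j: (-abs(w[j]), labels[j]))[:k]
    rows = [
        {
            "roi": labels[j],
            "network": groups.network_of(labels[j]) if groups is not None else "",
            "weight": w[j],
            "rank": i + 1,
        }
        for i, j in enumerate(order)
    ]
    return pd.DataFrame(rows)


def weight_heatmap_table(results: dict, labels) -> pd.DataFrame:
    """Methods x features table of averaged signed weights."""
    labels = [str(x) for x in labels]
    table = {}
    for method, w in results.items():
        w = np.asarray(w, dtype=float).ravel()
        if w.size != len(labels):
            raise ValidationError(
                f"{method}: weight length {w.size} != {len(labels)} labels"
            )
        table[method] = w
    return pd.DataFrame(table, index=labels).T


def plot_weight_heatmap(table: pd.DataFrame, path=None, cmap="RdBu_r"):
    """Render the methods x features weight table as a heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.12 * table.shape[1]), 1 + 0.5 * table.shape[0]))
    vmax = np.nanmax(np.abs(table.to_numpy())) or 1.0
    im = ax.imshow(table.to_numpy(), aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_yticks(range(table.shape[0]), table.index)
    ax.set_xlabel("ROI")
    fig.colorbar(im, ax=ax, label="canonical weight")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
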
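"""Network figures: strong-coherence edges with degree-coloured nodes."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_network"]


def plot_network(adj, node_labels=None, ax=None, title: str = ""):
    """Circular-layout plot of a binary adjacency network.

    Node colour encodes degree (connections to other electrodes); drawn
    edges are the strong-coherence pairs surviving the percentile
    threshold.
    """
    import matplotlib.pyplot as plt

    matrix = np.asarray(getattr(adj, "matrix", adj))
    n = matrix.shape[0]
    if node_labels is None:
        node_labels = getattr(adj, "node_labels", None) or [str(i) for i in range(n)]
    theta = 2 * np.pi * np.arange(n) / n
    xy = np.c_[np.cos(theta), np.sin(theta)]
    deg = matrix.sum(axis=1)

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for i, j in np.argwhere(np.triu(matrix, k=1)):
        ax.plot(xy[[i, j], 0], xy[[i, j], 1], color="0.7", lw=0.5, zorder=1)
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=deg, cmap="viridis", s=60, zorder=2)
    for i, label in enumerate(node_labels):
        ax.annotate(label, 1.08 * xy[i], fontsize=5, ha="center", va="center")
    ax.figure.colorbar(sc, ax=ax, shrink=0.7, label="degree")
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    return ax
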
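"""Scatter-plot export for 2-D morphological maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .embedding import Embedding

__all__ = ["scatter_embedding"]


def scatter_embedding(embedding: Embedding, labels, path, title: str | None = None) -> None:
    """Save the embedding as a scatter plot with points colored by a labeling."""
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    for value in np.unique(labels):
        sel = labels == value
        ax.scatter(embedding.coords[sel, 0], embedding.coords[sel, 1], s=8, label=str(value))
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, markerscale=1.5, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
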
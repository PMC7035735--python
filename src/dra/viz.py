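"""2-D visualization of embeddings colored by cell type.

Supports the direct K=2 projection plot and the two-step procedure that
projects to K=10 with a trained model and then runs t-SNE down to 2-D,
plus the convention of restricting crowded datasets to their ten most
abundant cell types before plotting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .io import LabelVector

__all__ = ["Embedding2D", "two_step_embed", "filter_top_cell_types", "scatter_plot"]


@dataclass
class Embedding2D:
    coordinates: np.ndarray
    labels: LabelVector
    method_tag: str = ""

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValueError("coordinates must be M × 2")
        if len(self.labels) != self.coordinates.shape[0]:
            raise ValueError("labels length must match the number of points")

    def to_frame(self, cell_ids=None) -> pd.DataFrame:
        ids = cell_ids if cell_ids is not None else list(range(len(self.labels)))
        return pd.DataFrame({
            "cell_id": ids,
            "x": self.coordinates[:, 0],
            "y": self.coordinates[:, 1],
            "label": self.labels.labels,
        })


def two_step_embed(model, x, labels: LabelVector, perplexity: float = 30.0,
                   seed: int = 0, allow_any_latent_dim: bool = False) -> Embedding2D:
    """Project with a K=10 model, then t-SNE the latent codes to 2-D."""
    if model.config.latent_dim != 10 and not allow_any_latent_dim:
        raise ValueError(
            f"two-step visualization expects a K=10 model (got K="
            f"{model.config.latent_dim}); pass allow_any_latent_dim=True to override"
        )
    latent = model.project(x)
    perp = min(perplexity, (latent.shape[0] - 1) / 3.0)
    coords = TSNE(n_components=2, perplexity=perp, random_state=seed).fit_transform(latent)
    return Embedding2D(np.asarray(coords, dtype=np.float64), labels,
                       method_tag=f"DR-A (K={model.config.latent_dim}) + t-SNE")


def filter_top_cell_types(x, labels: LabelVector, n_types: int = 10):
    """Keep cells whose label is among the ``n_types`` most frequent.

    Frequency ties are broken by lexicographic label order. ``x`` may be
    any array-like with cells as the leading axis.
    """
    if n_types < 1:
        raise ValueError("n_types must be at least 1")
    counts = Counter(str(l) for l in labels.labels)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    keep = {lab for lab, _ in ranked[:n_types]}
    idx = [i for i, l in enumerate(labels.labels) if str(l) in keep]
    arr = np.asarray(x)
    return arr[idx], labels.subset(idx)


def scatter_plot(embedding: Embedding2D, path: str) -> str:
    """One point per cell, colored by label, legend included. Writes PNG/SVG."""
    if embedding.coordinates.shape[0] == 0:
        raise ValueError("cannot plot an empty embedding")
    # stable palette: labels ordered by decreasing frequency
    counts = Counter(str(l) for l in embedding.labels.labels)
    ordered = [lab for lab, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    cmap = plt.get_cmap("tab20")
    fig, ax = plt.subplots(figsize=(6, 5))
    lab_arr = np.asarray([str(l) for l in embedding.labels.labels])
    for i, lab in enumerate(ordered):
        mask = lab_arr == lab
        ax.scatter(embedding.coordinates[mask, 0], embedding.coordinates[mask, 1],
                   s=8, color=cmap(i % 20), label=lab, linewidths=0)
    ax.set_title(embedding.method_tag or "embedding")
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.legend(markerscale=2, fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
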
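"""Clustering evaluation: K-means on embeddings, NMI against ground truth.

Embeddings are scored by running K-means with k set to the number of
ground-truth cell types and computing normalized mutual information
NMI = MI(X;Y) / √(H(X)·H(Y)) between the cluster assignments X and the
true labels Y. The NMI is computed here from the joint contingency table
(natural log; the ratio is base-invariant) rather than delegated to a
library, and is cross-checked against scikit-learn in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .io import LabelVector, ProcessedMatrix

__all__ = ["ClusteringResult", "kmeans_cluster", "nmi", "evaluate_embedding", "run_baselines"]


@dataclass
class ClusteringResult:
    assignments: LabelVector
    k: int
    inertia: float
    seed: int

    def __post_init__(self):
        if len(set(self.assignments.labels)) > self.k:
            raise ValueError("more distinct assignments than clusters")


def kmeans_cluster(embedding, k: int, seed: int = 0) -> ClusteringResult:
    """K-means with k-means++ initialization and 10 restarts."""
    embedding = np.asarray(embedding, dtype=np.float64)
    if embedding.ndim != 2:
        raise ValueError("embedding must be a 2-D array (cells × dims)")
    if k < 1 or k > embedding.shape[0]:
        raise ValueError(f"k={k} out of range for {embedding.shape[0]} cells")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(embedding)
    return ClusteringResult(
        assignments=LabelVector([int(l) for l in labels]),
        k=k,
        inertia=float(km.inertia_),
        seed=seed,
    )


def nmi(predicted: LabelVector, truth: LabelVector) -> float:
    """NMI(X, Y) = MI / √(H(X)H(Y)) from the joint contingency table.

    Returns 0 (with a warning) when either labeling has a single class,
    where the normalization is degenerate.
    """
    x = predicted.as_array() if isinstance(predicted, LabelVector) else np.asarray(predicted)
    y = truth.as_array() if isinstance(truth, LabelVector) else np.asarray(truth)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("label vectors must be nonempty and of equal length")
    n = x.size
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    table = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(table, (xi, yi), 1.0)
    pxy = table / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    if hx == 0.0 or hy == 0.0:
        warnings.warn("single-class labeling: NMI defined as 0", stacklevel=2)
        return 0.0
    nz = pxy > 0
    mi = np.sum(pxy[nz] * (np.log(pxy[nz]) - np.log(np.outer(px, py)[nz])))
    return float(mi / np.sqrt(hx * hy))


def evaluate_embedding(embedding, truth: LabelVector, seed: int = 0) -> float:
    """K-means with k = number of true classes, scored by NMI."""
    k = truth.n_classes() if isinstance(truth, LabelVector) else len(set(truth))
    if k < 2:
        raise ValueError("ground truth must contain at least 2 classes")
    truth = truth if isinstance(truth, LabelVector) else LabelVector(list(truth))
    result = kmeans_cluster(embedding, k, seed=seed)
    return nmi(result.assignments, truth)


def run_baselines(data: ProcessedMatrix, methods, K: int, truth: LabelVector,
                  seed: int = 0, tsne_perplexity: float = 30.0) -> pd.DataFrame:
    """NMI of standard embedding methods (pca, tsne, umap) at latent dim K.

    t-SNE only supports K ≤ 3 and is reported as not applicable (NaN NMI)
    for larger K. Returns a DataFrame with columns method, K, seed, nmi,
    note.
    """
    X = np.asarray(data.values if isinstance(data, ProcessedMatrix) else data,
                   dtype=np.float64)
    rows = []
    for method in methods:
        method = method.lower()
        note = ""
        score = np.nan
        if method == "pca":
            emb = PCA(n_components=K, random_state=seed).fit_transform(X)
            score = evaluate_embedding(emb, truth, seed=seed)
        elif method == "tsne":
            if K > 3:
                note = "N/A: t-SNE supports at most 3 output dimensions"
            else:
                perp = min(tsne_perplexity, (X.shape[0] - 1) / 3.0)
                emb = TSNE(n_components=K, perplexity=perp,
                           random_state=seed).fit_transform(X)
                score = evaluate_embedding(emb, truth, seed=seed)
        elif method == "umap":
            try:
                from umap import UMAP
            except ImportError:  # pragma: no cover
                note = "N/A: umap-learn not installed"
            else:
                emb = UMAP(n_components=K, random_state=seed).fit_transform(X)
                score = evaluate_embedding(emb, truth, seed=seed)
        else:
            raise ValueError(f"unknown baseline method {method!r}")
        rows.append({"method": method, "K": K, "seed": seed, "nmi": score, "note": note})
    return pd.DataFrame(rows, columns=["method", "K", "seed", "nmi", "note"])
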
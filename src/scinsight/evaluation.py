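"""Evaluation metrics: integration score, adjusted Rand index, silhouette.

The integration score measures how well samples are mixed after
integration: for each cell it compares the frequency of its own sample
among its k nearest neighbors with that sample's frequency in the whole
population, and averages 1 minus the absolute difference. A score of 1
means every neighborhood reflects the global sample composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, silhouette_samples
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger("scinsight")

DEFAULT_K = 20  # matches the MNN neighbor count and the 20-PC convention


@dataclass
class NeighborSets:
    """k-nearest-neighbor sets over pooled cells, with sample assignments."""

    indices: np.ndarray   # (M, k) neighbor indices, self excluded
    sample_of: np.ndarray  # (M,) sample index per cell
    k: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices)
        self.sample_of = np.asarray(self.sample_of)
        M = len(self.sample_of)
        if self.indices.shape[0] != M:
            raise ValueError("indices and sample_of disagree on cell count")
        if (self.indices == np.arange(M)[:, None]).any():
            raise ValueError("a cell may not be its own neighbor")


def neighbor_sets(embedding: np.ndarray, sample_of, k: int = DEFAULT_K) -> NeighborSets:
    """Euclidean k-NN sets over all pooled cells (self excluded)."""
    embedding = np.asarray(embedding, float)
    sample_of = np.asarray(sample_of)
    M = embedding.shape[0]
    if M < 2:
        raise ValueError("need at least two cells")
    if k >= M:
        raise ValueError(f"k={k} must be smaller than the number of cells ({M})")
    nbrs = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    ind = nbrs.kneighbors(embedding, return_distance=False)
    out = np.empty((M, k), dtype=int)
    for i in range(M):
        row = ind[i][ind[i] != i][:k]
        if len(row) < k:  # self not returned (duplicate points); pad from end
            row = np.concatenate([row, ind[i][-(k - len(row)):]])
        out[i] = row
    return NeighborSets(out, sample_of, k)


def integration_score(neighbors: NeighborSets) -> float:
    """Mean over cells of 1 - |local own-sample frequency - global frequency|.

    The local frequency is over the k neighbors (self excluded); the
    global frequency is over all M cells including the cell itself.
    """
    sample_of = neighbors.sample_of
    M = len(sample_of)
    ids, counts = np.unique(sample_of, return_counts=True)
    global_freq = dict(zip(ids, counts / M))
    own = sample_of[neighbors.indices] == sample_of[:, None]
    local = own.mean(axis=1)
    glob = np.array([global_freq[s] for s in sample_of])
    return float(np.mean(1.0 - np.abs(local - glob)))


def pca_embedding(X: np.ndarray, n_components: int = 20,
                  random_state: int | None = 0) -> np.ndarray:
    """Project pooled expression onto the top principal components.

    The convention for scoring unintegrated data: cell-cell distances are
    taken in the space of the first 20 PCs of the processed matrix.
    """
    X = np.asarray(X, float)
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    return PCA(n_components=n_components, random_state=random_state).fit_transform(X)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (Hubert-Arabie)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("partitions must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))


def silhouette(embedding: np.ndarray, labels) -> tuple[np.ndarray, float]:
    """Per-cell silhouette values (Euclidean) and their median.

    Cells in singleton clusters get silhouette 0 by convention.
    """
    embedding = np.asarray(embedding, float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two clusters")
    if (counts == 1).any():
        logger.warning("%d singleton clusters: their cells score 0",
                       int((counts == 1).sum()))
    values = silhouette_samples(embedding, labels, metric="euclidean")
    return values, float(np.median(values))
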
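"""Cross-sample cell clustering on common-module expression.

Cells are clustered jointly across samples from their common-module
expression W_l2: rows are L2-normalized, a mutual-nearest-neighbor (MNN)
graph is built between (and within) samples, Louvain community detection
partitions the graph, and module expression is quantile-aligned within
each cluster for downstream visualization.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger("scinsight")

DEFAULT_N_NEIGHBORS = 20


@dataclass
class ModuleEmbedding:
    """Per-sample module expression matrices (cells x K) with sample IDs."""

    matrices: list[np.ndarray]
    sample_ids: list[str]
    normalized: bool = False

    @property
    def n_samples(self) -> int:
        return len(self.matrices)

    @property
    def n_cells(self) -> int:
        return sum(m.shape[0] for m in self.matrices)

    @property
    def offsets(self) -> np.ndarray:
        """Global index of each sample's first cell (pooled, study order)."""
        sizes = [m.shape[0] for m in self.matrices]
        return np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(int)

    def stacked(self) -> np.ndarray:
        return np.vstack(self.matrices)

    def sample_index_of_cells(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_samples),
                         [m.shape[0] for m in self.matrices])


@dataclass
class MnnGraph:
    """Undirected MNN graph over all pooled cells."""

    n_nodes: int
    edges: np.ndarray  # (E, 2) global cell indices, u < v
    n_c: int

    def adjacency(self) -> sp.csr_matrix:
        if len(self.edges) == 0:
            return sp.csr_matrix((self.n_nodes, self.n_nodes))
        u, v = self.edges[:, 0], self.edges[:, 1]
        a = sp.coo_matrix((np.ones(len(u)), (u, v)), shape=(self.n_nodes,) * 2)
        return (a + a.T).tocsr()


@dataclass
class ClusterResult:
    """Joint clustering output: labels, the MNN graph, aligned expression."""

    labels: np.ndarray
    graph: MnnGraph
    aligned: ModuleEmbedding


def _as_embedding(x) -> ModuleEmbedding:
    if isinstance(x, ModuleEmbedding):
        return x
    # a fitted FactorModel (duck-typed to avoid an import cycle)
    if hasattr(x, "W2"):
        return ModuleEmbedding([w.copy() for w in x.W2], list(x.sample_ids))
    raise TypeError("expected a ModuleEmbedding or fitted FactorModel")


def normalize_rows(embedding: ModuleEmbedding) -> ModuleEmbedding:
    """L2-normalize every cell's module-expression row; zero rows stay zero."""
    out = []
    for mat, sid in zip(embedding.matrices, embedding.sample_ids):
        norms = np.linalg.norm(mat, axis=1)
        zero = norms == 0
        if zero.any():
            logger.warning("sample '%s': %d cells with zero module expression "
                           "left unnormalized", sid, int(zero.sum()))
        out.append(mat / np.where(zero, 1.0, norms)[:, None])
    return ModuleEmbedding(out, list(embedding.sample_ids), normalized=True)


def build_mnn_graph(embedding: ModuleEmbedding, n_c: int = DEFAULT_N_NEIGHBORS,
                    include_within_sample: bool = True) -> MnnGraph:
    """Build the mutual-nearest-neighbor graph over all pooled cells.

    For every ordered sample pair (l, l'), the ``n_c`` Euclidean nearest
    neighbors in sample l' are found for each cell of sample l (within the
    same sample, the cell itself is excluded). Two cells are connected iff
    each is among the other's neighbors. A query sample with fewer than
    ``n_c`` cells contributes all its cells as neighbors.
    """
    mats = embedding.matrices
    L = len(mats)
    offsets = embedding.offsets
    M = embedding.n_cells

    # nn[l][lp] : boolean sparse (m_l x m_lp), cell i of l has neighbor i' of lp
    nn: list[list[sp.csr_matrix]] = [[None] * L for _ in range(L)]
    for lp in range(L):
        m_lp = mats[lp].shape[0]
        index = NearestNeighbors(metric="euclidean").fit(mats[lp])
        for l in range(L):
            if l == lp and not include_within_sample and L > 1:
                continue
            if l == lp:
                k = min(n_c + 1, m_lp)
            else:
                k = min(n_c, m_lp)
            ind = index.kneighbors(mats[l], n_neighbors=k, return_distance=False)
            rows = np.repeat(np.arange(mats[l].shape[0]), ind.shape[1])
            cols = ind.ravel()
            if l == lp:
                keep = rows != cols
                rows, cols = rows[keep], cols[keep]
            nn[l][lp] = sp.csr_matrix(
                (np.ones(len(rows), bool), (rows, cols)),
                shape=(mats[l].shape[0], m_lp))

    edges = []
    for l in range(L):
        for lp in range(l, L):
            if nn[l][lp] is None or nn[lp][l] is None:
                continue
            mutual = nn[l][lp].multiply(nn[lp][l].T).tocoo()
            u = mutual.row + offsets[l]
            v = mutual.col + offsets[lp]
            if l == lp:
                keep = u < v
                u, v = u[keep], v[keep]
            edges.append(np.column_stack([u, v]))
    edges = np.vstack(edges) if edges else np.empty((0, 2), dtype=int)
    return MnnGraph(M, edges.astype(int), n_c)


def louvain_cluster(graph: MnnGraph, resolution: float = 1.0,
                    seed: int | None = 0) -> np.ndarray:
    """Louvain community detection on the MNN graph (unweighted edges).

    Isolated cells become singleton clusters. Deterministic for a given
    ``seed``.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    g = ig.Graph(n=graph.n_nodes, edges=[tuple(e) for e in graph.edges])
    ig.set_random_number_generator(_random.Random(seed))
    try:
        part = g.community_multilevel(resolution=resolution)
    finally:
        ig.set_random_number_generator(_random)
    labels = np.asarray(part.membership, dtype=int)
    n_isolated = int((np.asarray(g.degree()) == 0).sum())
    if n_isolated:
        logger.warning("%d isolated cells assigned to singleton clusters", n_isolated)
    return labels


def quantile_align(embedding: ModuleEmbedding, labels: np.ndarray) -> ModuleEmbedding:
    """Quantile-normalize module expression across samples within clusters.

    Within each cluster and module, every sample's value distribution is
    mapped onto the empirical quantiles of the reference sample (the
    sample with the most cells in that cluster; ties go to the earlier
    sample). Samples with fewer than two cells in a cluster are passed
    through unchanged. Rank order within each sample is preserved.
    """
    labels = np.asarray(labels)
    if len(labels) != embedding.n_cells:
        raise ValueError("labels must cover all cells")
    out = [m.copy() for m in embedding.matrices]
    sample_of = embedding.sample_index_of_cells()
    offsets = embedding.offsets
    L = embedding.n_samples
    for c in np.unique(labels):
        in_c = labels == c
        counts = np.array([(in_c & (sample_of == l)).sum() for l in range(L)])
        ref = int(np.argmax(counts))
        if counts[ref] < 1:
            continue
        ref_rows = np.flatnonzero(in_c & (sample_of == ref)) - offsets[ref]
        for l in range(L):
            if l == ref or counts[l] == 0:
                continue
            if counts[l] < 2:
                logger.warning("cluster %s: sample %d has a single cell; "
                               "left unaligned", c, l)
                continue
            rows = np.flatnonzero(in_c & (sample_of == l)) - offsets[l]
            for k in range(out[l].shape[1]):
                x = out[l][rows, k]
                order = np.argsort(x, kind="stable")
                p = np.linspace(0.0, 1.0, len(rows))
                mapped = np.quantile(embedding.matrices[ref][ref_rows, k], p)
                aligned = np.empty_like(x)
                aligned[order] = mapped
                out[l][rows, k] = aligned
    return ModuleEmbedding(out, list(embedding.sample_ids),
                           normalized=embedding.normalized)


def cluster_cells(model, n_c: int = DEFAULT_N_NEIGHBORS, resolution: float = 1.0,
                  seed: int | None = 0,
                  include_within_sample: bool = True) -> ClusterResult:
    """Full clustering pipeline on a fitted model's common-module expression.

    Composes :func:`normalize_rows`, :func:`build_mnn_graph`,
    :func:`louvain_cluster` and :func:`quantile_align`.
    """
    embedding = normalize_rows(_as_embedding(model))
    graph = build_mnn_graph(embedding, n_c=n_c,
                            include_within_sample=include_within_sample)
    labels = louvain_cluster(graph, resolution=resolution, seed=seed)
    aligned = quantile_align(embedding, labels)
    return ClusterResult(labels, graph, aligned)


class MNNLouvainClusterer(BaseEstimator, ClusterMixin):
    """Cluster cells across samples from a module-expression embedding.

    Parameters
    ----------
    n_neighbors : int, default 20
        Neighbors per sample pair in the MNN search.
    resolution : float, default 1.0
        Louvain modularity resolution.
    include_within_sample : bool, default True
        Whether MNN pairs within the same sample also become edges
        (keeps condition-unique populations connected when a condition
        has a single sample).
    random_state : int or None
        Louvain seed.

    Attributes
    ----------
    labels_ : ndarray of shape (n_cells,)
    graph_ : MnnGraph
    aligned_ : ModuleEmbedding
        Quantile-aligned module expression (per sample).
    """

    def __init__(self, n_neighbors: int = DEFAULT_N_NEIGHBORS,
                 resolution: float = 1.0, include_within_sample: bool = True,
                 random_state: int | None = 0):
        self.n_neighbors = n_neighbors
        self.resolution = resolution
        self.include_within_sample = include_within_sample
        self.random_state = random_state

    def fit(self, X, y=None, *, sample_labels=None):
        """Fit on a fitted factor model, a ModuleEmbedding, or a pooled
        cells x K array with per-cell ``sample_labels``."""
        if isinstance(X, np.ndarray):
            if sample_labels is None:
                raise ValueError("array input requires per-cell sample_labels")
            sample_labels = np.asarray(sample_labels)
            ids: list = []
            for s in sample_labels:
                if s not in ids:
                    ids.append(s)
            mats = [np.asarray(X, float)[sample_labels == s] for s in ids]
            X = ModuleEmbedding(mats, [str(s) for s in ids])
        result = cluster_cells(X, n_c=self.n_neighbors, resolution=self.resolution,
                               seed=self.random_state,
                               include_within_sample=self.include_within_sample)
        self.result_ = result
        self.labels_ = result.labels
        self.graph_ = result.graph
        self.aligned_ = result.aligned
        return self

    def fit_predict(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y, **fit_params).labels_
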
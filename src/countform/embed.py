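"""PCA embedding, k-NN graphs, the overlap statistic and graph clustering.

The benchmark pipeline embeds transformed counts with PCA, links each cell
to its k nearest neighbors by Euclidean distance, and compares two k-NN
graphs by the mean per-cell overlap of their neighbor sets

    overlap = (1 / no. cells) * sum_{c,d} N1_cd * N2_cd,

where N1, N2 are the binary adjacency matrices.  The overlap ranges from 0
to k; two independent random graphs on n cells have expected overlap
k^2/(n-1).  Cluster agreement is measured with the adjusted Rand index and
adjusted mutual information after walktrap community detection on the
undirected k-NN graph.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import scipy.sparse as sp
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score

from .transforms import SizeFactors, TransformedMatrix

__all__ = [
    "Embedding",
    "KnnGraph",
    "ClusterLabels",
    "pca_embed",
    "knn_graph",
    "knn_overlap",
    "cluster_graph",
    "ari",
    "ami",
    "size_factor_cca",
    "mean_variance_profile",
]


@dataclass
class Embedding:
    """Cells × d PCA scores (gene-centered, unscaled)."""

    coords: np.ndarray
    d: int
    centering: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape[1] != self.d:
            raise ValueError("coords width does not match d")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class KnnGraph:
    """Exactly-k nearest neighbors per cell, self excluded.

    ``neighbors`` is an (n_cells, k) integer array; row c lists the k
    nearest cells of c in order of increasing distance (ties by index).
    """

    neighbors: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.neighbors = np.asarray(self.neighbors, dtype=np.int64)
        n, k = self.neighbors.shape
        if k != self.k:
            raise ValueError("neighbor array width does not match k")
        rows = np.arange(n)[:, None]
        if (self.neighbors == rows).any():
            raise ValueError("self-loop in k-NN graph")

    @property
    def n_cells(self) -> int:
        return self.neighbors.shape[0]

    def neighbor_sets(self) -> list[set[int]]:
        return [set(row) for row in self.neighbors]

    def adjacency(self) -> sp.csr_matrix:
        """Binary n × n adjacency with row sums k."""
        n, k = self.neighbors.shape
        rows = np.repeat(np.arange(n), k)
        return sp.csr_matrix(
            (np.ones(n * k), (rows, self.neighbors.ravel())), shape=(n, n)
        )


@dataclass
class ClusterLabels:
    """Per-cell integer community labels."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def pca_embed(t: TransformedMatrix | np.ndarray, d: int) -> Embedding:
    """Top-d principal components of the cells, after centering each gene.

    Genes are centered but not scaled (scaling is the separate z-score
    post-processing step).  Component signs are fixed by making the
    largest-magnitude gene loading of each component positive, so the
    embedding is deterministic.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if isinstance(t, TransformedMatrix):
        X = t.toarray()
    elif sp.issparse(t):
        X = t.toarray()
    else:
        X = np.asarray(t, dtype=float)
    # cells as rows for the SVD
    X = X.T - X.mean(axis=1)
    max_d = min(X.shape)
    if d > max_d:
        raise ValueError(f"d={d} exceeds min(n_cells, n_genes)={max_d}")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :d], S[:d], Vt[:d]
    # sign fix: largest-|loading| of each component made positive
    flip = np.sign(Vt[np.arange(d), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = U * S * flip
    return Embedding(coords=scores, d=d)


def _knn_from_points(X: np.ndarray, k: int, chunk: int = 1024) -> np.ndarray:
    """Exact brute-force k-NN with ties broken by lower cell index."""
    n = X.shape[0]
    sq = np.einsum("ij,ij->i", X, X)
    out = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (X[start:stop] @ X.T)
        np.maximum(d2, 0.0, out=d2)
        rows = np.arange(start, stop)
        d2[np.arange(stop - start), rows] = np.inf  # exclude self
        # stable sort on distance → equal distances ordered by cell index
        order = np.argsort(d2, axis=1, kind="stable")
        out[start:stop] = order[:, :k]
    return out


def knn_graph(e: Embedding | np.ndarray, k: int) -> KnnGraph:
    """Exact k nearest neighbors of each cell by Euclidean distance.

    Self is excluded; distance ties are broken in favour of the lower cell
    index, which makes duplicate points well-defined.
    """
    X = e.coords if isinstance(e, Embedding) else np.asarray(e, dtype=float)
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_cells={n}")
    return KnnGraph(neighbors=_knn_from_points(X, k), k=k)


def knn_overlap(a: KnnGraph, b: KnnGraph) -> float:
    """Mean per-cell neighbor-set intersection of two k-NN graphs.

    Equals (1/n) Σ_{c,d} N1_cd N2_cd for the binary adjacencies; ranges
    from 0 to k.
    """
    if a.n_cells != b.n_cells:
        raise ValueError("graphs have different cell sets")
    if a.k != b.k:
        raise ValueError("graphs have different k")
    inter = a.adjacency().multiply(b.adjacency()).sum()
    return float(inter) / a.n_cells


def cluster_graph(g: KnnGraph, seed: int = 0, steps: int = 4) -> ClusterLabels:
    """Walktrap community detection on the undirected k-NN graph.

    The directed k-NN relation is symmetrized; communities come from the
    random-walk-based agglomerative walktrap algorithm (4-step walks),
    cutting the dendrogram at maximum modularity.  Deterministic given the
    graph and seed.
    """
    adj = g.adjacency()
    sym = ((adj + adj.T) > 0).astype(np.int8).tocoo()
    mask = sym.row < sym.col
    edges = list(zip(sym.row[mask].tolist(), sym.col[mask].tolist()))
    graph = ig.Graph(n=g.n_cells, edges=edges, directed=False)
    ig.set_random_number_generator(random.Random(seed))
    dendrogram = graph.community_walktrap(steps=steps)
    clustering = dendrogram.as_clustering()
    return ClusterLabels(labels=np.asarray(clustering.membership))


def ari(a: ClusterLabels, b: ClusterLabels) -> float:
    """Adjusted Rand index between two clusterings (1 = identical)."""
    if len(a.labels) != len(b.labels):
        raise ValueError("labelings cover different cells")
    return float(adjusted_rand_score(a.labels, b.labels))


def ami(a: ClusterLabels, b: ClusterLabels) -> float:
    """Adjusted mutual information between two clusterings (1 = identical)."""
    if len(a.labels) != len(b.labels):
        raise ValueError("labelings cover different cells")
    return float(adjusted_mutual_info_score(a.labels, b.labels))


def size_factor_cca(e: Embedding, s: SizeFactors | np.ndarray, d: int = 10) -> float:
    """First canonical correlation between size factors and the top-d PCs.

    For a one-dimensional variable this equals the multiple correlation R
    of regressing s on the d score columns.  Values near 1 mean sequencing
    depth is strongly encoded in the embedding (a confounding diagnostic).
    """
    sv = s.s if isinstance(s, SizeFactors) else np.asarray(s, dtype=float)
    if d > e.d:
        raise ValueError(f"d={d} exceeds embedding dimension {e.d}")
    if np.std(sv) == 0:
        raise ValueError("size factors are constant; correlation undefined")
    X = e.coords[:, :d]
    Xc = X - X.mean(axis=0)
    yc = sv - sv.mean()
    coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    fitted = Xc @ coef
    denom = np.linalg.norm(fitted) * np.linalg.norm(yc)
    if denom == 0:
        return 0.0
    return float(np.clip((fitted @ yc) / denom, 0.0, 1.0))


def mean_variance_profile(t: TransformedMatrix | np.ndarray) -> np.ndarray:
    """Per-gene (mean, variance) pairs across cells, as an (n_genes, 2) array.

    The raw material of mean–variance diagnostics: a flat variance profile
    across the dynamic range indicates successful variance stabilization.
    """
    if isinstance(t, TransformedMatrix):
        values = t.values
    else:
        values = t
    if sp.issparse(values):
        mean = np.asarray(values.mean(axis=1)).ravel()
        n = values.shape[1]
        sq = np.asarray(values.multiply(values).sum(axis=1)).ravel()
        var = np.maximum((sq - n * mean**2) / (n - 1), 0.0) if n > 1 else np.zeros_like(mean)
    else:
        arr = np.asarray(values, dtype=float)
        mean = arr.mean(axis=1)
        var = arr.var(axis=1, ddof=1) if arr.shape[1] > 1 else np.zeros_like(mean)
    return np.column_stack([mean, var])
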
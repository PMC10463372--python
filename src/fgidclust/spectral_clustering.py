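"""Spectral clustering on a precomputed distance matrix.

Affinities use local scaling: ``W_xy = exp(-D_xy^2 / (sigma_x sigma_y))``
with ``sigma_x`` the distance from x to its m-th nearest neighbour
(default m = 7), so dense and sparse regions of the mixed-metric space get
comparable kernels without a global bandwidth.  Labels come from k-means
(greedy k-means++ seeding, 20 restarts) on the row-normalized eigenvectors
of the k smallest eigenvalues of the symmetric normalized Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .mixed_distance import DistanceMatrix

DEFAULT_NEIGHBOR = 7
KMEANS_RESTARTS = 20


@dataclass
class ClusteringResult:
    ids: list
    labels: np.ndarray
    k: int
    compactness: np.ndarray  # per-cluster mean within-cluster distance
    seed: int

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.ids):
            raise ValueError("labels and ids length mismatch")
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("labels out of range")

    def members(self, cluster: int) -> list:
        return [i for i, lab in zip(self.ids, self.labels) if lab == cluster]


def affinity_from_distances(D: DistanceMatrix, m: int = DEFAULT_NEIGHBOR) -> np.ndarray:
    """Locally scaled Gaussian affinity; symmetric, zero diagonal."""
    n = D.n
    if not (1 <= m < n):
        raise ValueError("need n > m >= 1")
    d = D.d
    # column 0 of the sorted row is the self-distance 0; position m is the
    # m-th nearest neighbour
    sigma = np.sort(d, axis=1)[:, m]
    if sigma.max() == 0:
        raise ValueError("all-zero distance matrix: no scale for affinities")
    pos = sigma[sigma > 0]
    sigma = np.where(sigma == 0, pos.min(), sigma)
    w = np.exp(-(d ** 2) / np.outer(sigma, sigma))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return w


def spectral_embedding(W: np.ndarray, kmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of the symmetric normalized Laplacian.

    Returns the ``kmax`` smallest eigenvalues and their eigenvectors
    (columns).  Raises on isolated (zero-degree) vertices, naming them.
    """
    deg = W.sum(axis=1)
    isolated = np.flatnonzero(deg <= 0)
    if isolated.size:
        raise ValueError(f"isolated vertices (zero degree) at positions {isolated.tolist()}")
    inv_sqrt = 1.0 / np.sqrt(deg)
    lap = -W * np.outer(inv_sqrt, inv_sqrt)
    np.fill_diagonal(lap, 1.0)
    lap = 0.5 * (lap + lap.T)
    vals, vecs = eigh(lap, subset_by_index=[0, kmax - 1])
    return vals, vecs


def embedding_rows(vecs: np.ndarray, k: int) -> np.ndarray:
    """First-k eigenvector rows normalized to the unit sphere (zero rows
    are left as zero)."""
    emb = vecs[:, :k].copy()
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    nz = norms[:, 0] > 0
    emb[nz] /= norms[nz]
    return emb


def kmeans_labels(embedding: np.ndarray, k: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=k, init="k-means++", n_init=KMEANS_RESTARTS,
                random_state=seed % (2 ** 31))
    return km.fit_predict(embedding)


def cluster_compactness(D: DistanceMatrix, labels: np.ndarray, k: int) -> np.ndarray:
    """Mean within-cluster pairwise distance in the original metric;
    singletons get 0."""
    comp = np.zeros(k)
    for c in range(k):
        idx = np.flatnonzero(labels == c)
        if idx.size > 1:
            sub = D.d[np.ix_(idx, idx)]
            comp[c] = sub.sum() / (idx.size * (idx.size - 1))
    return comp


def spectral_embed_cluster(W: np.ndarray, k: int, seed: int,
                           distances: DistanceMatrix) -> ClusteringResult:
    """Embed with the k smallest Laplacian eigenvectors and cluster.

    Compactness is measured in the original distance matrix, not the
    embedding.
    """
    n = W.shape[0]
    if not (2 <= k <= n // 2):
        raise ValueError(f"k={k} outside [2, n/2] for n={n}")
    _, vecs = spectral_embedding(W, k)
    emb = embedding_rows(vecs, k)
    labels = kmeans_labels(emb, k, seed)
    comp = cluster_compactness(distances, labels, k)
    return ClusteringResult(ids=list(distances.ids), labels=labels, k=k,
                            compactness=comp, seed=seed)


def cluster_distance_matrix(D: DistanceMatrix, k: int, seed: int,
                            m: int = DEFAULT_NEIGHBOR) -> ClusteringResult:
    """Convenience: affinity + spectral embedding + k-means in one call."""
    W = affinity_from_distances(D, m=m)
    return spectral_embed_cluster(W, k, seed, D)
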
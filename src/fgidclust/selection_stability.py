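"""Choosing k with the S-Dbw validity index and certifying stability.

S-Dbw sums two non-negative terms: average within-cluster scatter relative
to the whole-data variance, and the average density at inter-centroid
midpoints relative to the density at the centroids themselves.  Its minimum
over k marks the preferred number of clusters.  Both terms presuppose a
low-dimensional coordinate space — in high dimension the density radius
catches no points and the scatter term decays monotonically in k — so the
selector evaluates the index in a fixed low-dimensional classical-MDS
representation of the mixed distance matrix, one space shared by every k,
while the labels themselves still come from the per-k spectral embedding.

Stability follows a record-deletion protocol: for each subsampling rate a
small fraction of records is removed, the whole distance-plus-spectral
pipeline is re-run on the remainder, and the relabelled solution is scored
against the full-data reference with Hungarian-matched clustering accuracy
(CA).  The solution is called stable when mean CA at the selected k
exceeds a threshold (default 0.85).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cohort_io import CohortTable
from .mixed_distance import DistanceMatrix, pairwise_distances
from .spectral_clustering import (DEFAULT_NEIGHBOR, ClusteringResult,
                                  affinity_from_distances, cluster_compactness,
                                  embedding_rows, kmeans_labels,
                                  spectral_embedding)

DEFAULT_K_RANGE = range(2, 16)
DEFAULT_EVAL_DIM = 3
DEFAULT_RATES = (0.02, 0.04, 0.06, 0.08, 0.10)
DEFAULT_REPS = 10
DEFAULT_CA_THRESHOLD = 0.85


def child_seed(master: int, *keys) -> int:
    """Deterministic per-stage seed below 2**31 derived from a master seed.

    String keys are folded to stable integers so call sites can name
    stages (e.g. ``child_seed(seed, "kmeans", k)``).
    """
    ints = [master] + [
        k if isinstance(k, (int, np.integer)) else abs(hash_str(k)) for k in keys
    ]
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1)[0] % (2 ** 31))


def hash_str(s: str) -> int:
    # stable across processes (builtin hash() is salted)
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2 ** 31)
    return h


# ---------------------------------------------------------------------------
# S-Dbw
# ---------------------------------------------------------------------------

def mds_coordinates(D: DistanceMatrix, dim: int = DEFAULT_EVAL_DIM) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates of a distance matrix.

    Double-centers the squared distances and keeps the ``dim`` leading
    non-negative eigendirections; the low-dimensional space in which the
    S-Dbw validity index is evaluated.
    """
    n = D.n
    if dim >= n:
        raise ValueError("dim must be below the number of records")
    d2 = D.d ** 2
    row = d2.mean(axis=1)
    b = -0.5 * (d2 - row[:, None] - row[None, :] + d2.mean())
    from scipy.linalg import eigh as _eigh
    vals, vecs = _eigh(b, subset_by_index=[n - dim, n - 1])
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    return vecs * np.sqrt(np.maximum(vals, 0.0))

def sdbw_index(embedding: np.ndarray, labels: np.ndarray, k: int | None = None
               ) -> tuple[float, float, float]:
    """Return ``(scatter, density, index)`` with ``index = scatter + density``.

    Scatter is the mean norm of per-cluster per-coordinate variance vectors
    over the norm of the whole-data variance vector.  Density compares, for
    every cluster pair, the point count within radius ``stdev`` of the
    inter-centroid midpoint to the larger of the counts at the two
    centroids (floored at 1), where
    ``stdev = (1/k) * sqrt(sum_i ||var(C_i)||)``.
    """
    x = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if k is None:
        k = len(uniq)
    if len(uniq) != k:
        raise ValueError(f"expected {k} non-empty clusters, found {len(uniq)}")
    if k < 2:
        raise ValueError("need at least 2 clusters")

    total_var = x.var(axis=0)
    total_norm = float(np.linalg.norm(total_var))
    if total_norm == 0:
        raise ValueError("whole-data variance is zero")

    centroids = np.vstack([x[labels == c].mean(axis=0) for c in uniq])
    var_norms = np.array([np.linalg.norm(x[labels == c].var(axis=0)) for c in uniq])
    scatter = float(var_norms.mean() / total_norm)
    stdev = float(np.sqrt(var_norms.sum()) / k)

    def dens(z: np.ndarray, pts: np.ndarray) -> int:
        return int((np.linalg.norm(pts - z, axis=1) <= stdev).sum())

    density = 0.0
    for i in range(k):
        pts_i = x[labels == uniq[i]]
        for j in range(i + 1, k):
            pts_j = x[labels == uniq[j]]
            union = np.vstack([pts_i, pts_j])
            mid = 0.5 * (centroids[i] + centroids[j])
            d_mid = dens(mid, union)
            d_max = max(dens(centroids[i], union), dens(centroids[j], union), 1)
            density += 2.0 * d_mid / d_max  # both (i,j) and (j,i)
    density = float(density / (k * (k - 1)))
    return scatter, density, scatter + density


@dataclass
class SdbwCurve:
    k_values: list[int]
    scatter: list[float]
    density: list[float]
    index: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "scatter": self.scatter,
                             "density": self.density, "index": self.index})

    def argmin_k(self) -> int:
        """k with minimal index; the smallest such k on ties."""
        return int(self.k_values[int(np.argmin(self.index))])


@dataclass
class SelectionResult:
    curve: SdbwCurve
    k_star: int
    result: ClusteringResult
    distances: DistanceMatrix
    labels_by_k: dict[int, np.ndarray]


def select_and_cluster(table: CohortTable, feature_set: str,
                       k_range=DEFAULT_K_RANGE, seed: int = 0,
                       lam: float = 0.1, bins: int = 8,
                       m: int = DEFAULT_NEIGHBOR,
                       eval_dim: int = DEFAULT_EVAL_DIM) -> SelectionResult:
    """Distance + spectral pipeline over a k range, scored by S-Dbw.

    The distance matrix, affinity, and Laplacian eigenvectors are computed
    once; each k re-uses the first k eigenvectors (its own embedding) and
    its own seeded k-means.  S-Dbw is evaluated for every k in one fixed
    ``eval_dim``-dimensional MDS representation of the distance matrix.
    """
    ks = sorted(int(k) for k in k_range)
    n = table.n_records
    if ks[-1] > n // 2:
        raise ValueError(f"k_max={ks[-1]} exceeds n/2={n // 2}")
    D = pairwise_distances(table, feature_set, lam=lam, bins=bins)
    W = affinity_from_distances(D, m=m)
    _, vecs = spectral_embedding(W, ks[-1])
    eval_space = mds_coordinates(D, eval_dim)

    scatter, density, index = [], [], []
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        emb = embedding_rows(vecs, k)
        labels = kmeans_labels(emb, k, child_seed(seed, "kmeans", k))
        labels_by_k[k] = labels
        s, d, i = sdbw_index(eval_space, labels, k)
        scatter.append(s)
        density.append(d)
        index.append(i)

    curve = SdbwCurve(ks, scatter, density, index)
    k_star = curve.argmin_k()
    best = ClusteringResult(
        ids=list(D.ids), labels=labels_by_k[k_star], k=k_star,
        compactness=cluster_compactness(D, labels_by_k[k_star], k_star),
        seed=seed,
    )
    return SelectionResult(curve, k_star, best, D, labels_by_k)


def select_num_clusters(table: CohortTable, feature_set: str,
                        k_range=DEFAULT_K_RANGE, seed: int = 0,
                        lam: float = 0.1, bins: int = 8,
                        m: int = DEFAULT_NEIGHBOR) -> tuple[SdbwCurve, int]:
    """S-Dbw curve over the k range and the selected k (curve minimum)."""
    sel = select_and_cluster(table, feature_set, k_range, seed, lam, bins, m)
    return sel.curve, sel.k_star


# ---------------------------------------------------------------------------
# Hungarian-matched clustering accuracy and subsampling stability
# ---------------------------------------------------------------------------

def hungarian_accuracy(labels_a, labels_b) -> float:
    """Best one-to-one cluster-matching agreement fraction in [0, 1]."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("labelings must be non-empty and equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    cont = np.bincount(ai * kb + bi, minlength=ka * kb).reshape(ka, kb)
    rows, cols = linear_sum_assignment(cont, maximize=True)
    return float(cont[rows, cols].sum() / a.size)


@dataclass
class StabilityReport:
    rates: list[float]
    repetitions: int
    k_range: list[int]
    ca: np.ndarray  # rates x repetitions x k
    mean_ca_per_k: dict[int, float]
    threshold: float
    selected_k: int
    passed: bool
    mode: str = "removed"

    def mean_ca(self) -> float:
        return self.mean_ca_per_k[self.selected_k]

    def to_dict(self) -> dict:
        return {
            "rates": self.rates,
            "repetitions": self.repetitions,
            "k_range": self.k_range,
            "ca": self.ca.tolist(),
            "mean_ca_per_k": {str(k): v for k, v in self.mean_ca_per_k.items()},
            "threshold": self.threshold,
            "selected_k": self.selected_k,
            "passed": self.passed,
            "mode": self.mode,
        }


def stability_analysis(table: CohortTable, feature_set: str,
                       k_range=DEFAULT_K_RANGE, rates=DEFAULT_RATES,
                       reps: int = DEFAULT_REPS, seed: int = 0,
                       threshold: float = DEFAULT_CA_THRESHOLD,
                       selected_k: int | None = None, mode: str = "removed",
                       lam: float = 0.1, bins: int = 8,
                       m: int = DEFAULT_NEIGHBOR) -> StabilityReport:
    """Subsampling stability of the full pipeline.

    Reference labels come from clustering the complete table at each k.
    Per (rate, repetition): delete ``ceil(rate * n)`` records uniformly at
    random (``mode="retained"`` instead keeps that fraction), refit the
    distance statistics and re-cluster the remainder, then score Hungarian
    CA against the reference restricted to the retained records.  The same
    per-k k-means seed is used for reference and subsample runs, so a
    rate of 0 reproduces the reference exactly.
    """
    ks = sorted(int(k) for k in k_range)
    n = table.n_records
    max_removed = max(rates) if mode == "removed" else 1 - min(rates)
    if n * (1 - max_removed) < 2 * ks[-1]:
        raise ValueError("subsample too small for the requested k range")
    if selected_k is None:
        if len(ks) != 1:
            raise ValueError("selected_k is required when scanning several k")
        selected_k = ks[0]
    if selected_k not in ks:
        raise ValueError(f"selected_k={selected_k} not in k_range")

    # full-data reference labelings
    D = pairwise_distances(table, feature_set, lam=lam, bins=bins)
    W = affinity_from_distances(D, m=m)
    _, vecs = spectral_embedding(W, ks[-1])
    reference = {
        k: kmeans_labels(embedding_rows(vecs, k), k, child_seed(seed, "kmeans", k))
        for k in ks
    }

    ca = np.zeros((len(rates), reps, len(ks)))
    all_idx = np.arange(n)
    for ri, rate in enumerate(rates):
        for rep in range(reps):
            rng = np.random.default_rng(child_seed(seed, "subsample", ri, rep))
            n_pick = int(np.ceil(rate * n))
            pick = rng.choice(n, size=n_pick, replace=False)
            if mode == "removed":
                keep = np.setdiff1d(all_idx, pick)
            elif mode == "retained":
                keep = np.sort(pick)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            sub = table.subset_records([table.record_ids[i] for i in keep])
            D_sub = pairwise_distances(sub, feature_set, lam=lam, bins=bins)
            W_sub = affinity_from_distances(D_sub, m=m)
            _, vecs_sub = spectral_embedding(W_sub, ks[-1])
            for ki, k in enumerate(ks):
                labels_sub = kmeans_labels(embedding_rows(vecs_sub, k), k,
                                           child_seed(seed, "kmeans", k))
                ca[ri, rep, ki] = hungarian_accuracy(labels_sub, reference[k][keep])

    mean_per_k = {k: float(ca[:, :, ki].mean()) for ki, k in enumerate(ks)}
    return StabilityReport(
        rates=list(rates), repetitions=reps, k_range=ks, ca=ca,
        mean_ca_per_k=mean_per_k, threshold=threshold,
        selected_k=selected_k, passed=bool(mean_per_k[selected_k] >= threshold),
        mode=mode,
    )
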
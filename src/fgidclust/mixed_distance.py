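"""Mixed ordinal/continuous record distance with inter-attribute context.

The metric combines four ingredients, one per source of information in a
mixed questionnaire table:

* **intra-attribute ordinal term** — the distance between two levels of an
  ordinal variable is the gap between their midpoint cumulative
  probabilities, ``|F_mid(a) - F_mid(b)|`` with
  ``F_mid(c) = P(X <= c) - p(c)/2``, so rarely used levels sit close to
  their neighbours and the term is additive along the level order;
* **inter-attribute ordinal term** — two levels of variable *j* also differ
  to the extent that they induce different conditional distributions on the
  other variables; that difference is measured by the square root of the
  normalized Jensen–Shannon divergence between the conditionals (over a
  context variable's levels if ordinal, over equal-frequency bins if
  continuous);
* **mutual-information weighting** — context variables contribute in
  proportion to their normalized mutual information with *j*, so
  uninformative contexts do not dilute the distance;
* **numeric block** — continuous variables enter through a shrinkage
  Mahalanobis distance, ``S_l = (1-l) S + l diag(S)``, which carries their
  intra- and inter-attribute correlation structure.

Blocks are balanced so that each block's mean squared contribution across
record pairs equals its share of the attribute count.  The result is
symmetric, non-negative, and zero on identical records; the triangle
inequality is not guaranteed (nor needed by spectral clustering).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .cohort_io import CohortTable

_ALPHA = 0.5  # additive smoothing per conditional-table cell


def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """JSD in nats: ``H((p+q)/2) - (H(p)+H(q))/2``; bounded by ``ln 2``."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probability vectors must be non-negative")
    m = 0.5 * (p + q)
    jsd = _entropy(m) - 0.5 * (_entropy(p) + _entropy(q))
    return float(max(jsd, 0.0))


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def normalized_mutual_information(j: str, k: str, table: CohortTable, bins: int = 8) -> float:
    """NMI between two variables, ``I / sqrt(H_j H_k)``; continuous
    variables are first cut into ``bins`` equal-frequency bins.

    Returns 0 when either variable is constant.
    """
    a = _codes_for(table, j, bins)
    b = _codes_for(table, k, bins)
    return _nmi_from_codes(a, b)


def _codes_for(table: CohortTable, name: str, bins: int) -> np.ndarray:
    var = table.schema[name]
    col = table.data[name].to_numpy(dtype=float)
    if var.vtype == "ordinal":
        return col.astype(np.int64)
    return _equal_frequency_codes(col, bins)


def _equal_frequency_codes(values: np.ndarray, bins: int) -> np.ndarray:
    """Digitize into <= ``bins`` equal-frequency bins (duplicate quantile
    edges collapse, so heavily tied columns yield fewer bins)."""
    qs = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, values, side="right").astype(np.int64)


def _nmi_from_codes(a: np.ndarray, b: np.ndarray) -> float:
    n = len(a)
    ka, kb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb) / n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    ha, hb = _entropy(pa), _entropy(pb)
    if ha <= 0 or hb <= 0:
        return 0.0
    mi = _entropy(pa) + _entropy(pb) - _entropy(joint.ravel())
    return float(min(max(mi / np.sqrt(ha * hb), 0.0), 1.0))


@dataclass
class AttributeStats:
    """Distributional statistics backing the mixed distance, estimated from
    one cohort table and one feature set."""

    feature_set: str
    ordinal_names: list[str]
    continuous_names: list[str]
    levels: dict[str, int]
    marginals: dict[str, np.ndarray]
    midpoint_cdf: dict[str, np.ndarray]
    conditionals: dict[tuple[str, str], np.ndarray]
    num_conditionals: dict[tuple[str, str], np.ndarray]
    nmi: pd.DataFrame
    cov: np.ndarray | None
    lam: float
    bins: int
    _chol: np.ndarray | None = None  # lower Cholesky factor of shrunk covariance

    @property
    def context_names(self) -> list[str]:
        return self.ordinal_names + self.continuous_names


def fit_attribute_stats(table: CohortTable, feature_set: str = "gi_only",
                        lam: float = 0.1, bins: int = 8) -> AttributeStats:
    """Estimate marginals, conditionals, NMI, and the shrunk covariance.

    Conditional tables receive additive smoothing of 0.5 per cell before
    normalization; marginals and NMI are unsmoothed.  Raises if a
    continuous variable has zero variance (the Mahalanobis block would be
    degenerate).
    """
    if table.n_records < 10:
        raise ValueError("need at least 10 records to fit attribute statistics")
    variables = table.schema.subset(feature_set)
    ordinal = [v for v in variables if v.vtype == "ordinal"]
    continuous = [v for v in variables if v.vtype == "continuous"]

    codes: dict[str, np.ndarray] = {}
    for v in ordinal:
        codes[v.name] = table.data[v.name].to_numpy(dtype=np.int64)
    for v in continuous:
        col = table.data[v.name].to_numpy(dtype=float)
        if np.var(col) == 0:
            raise ValueError(f"continuous variable {v.name!r} has zero variance")
        codes[v.name] = _equal_frequency_codes(col, bins)

    n = table.n_records
    marginals, midpoint = {}, {}
    levels = {v.name: v.levels for v in ordinal}
    for v in ordinal:
        counts = np.bincount(codes[v.name], minlength=v.levels).astype(float)
        p = counts / n
        marginals[v.name] = p
        midpoint[v.name] = np.cumsum(p) - 0.5 * p

    def _cond(src: np.ndarray, n_src: int, tgt: np.ndarray, n_tgt: int) -> np.ndarray:
        tab = np.bincount(src * n_tgt + tgt, minlength=n_src * n_tgt)
        tab = tab.reshape(n_src, n_tgt).astype(float) + _ALPHA
        return tab / tab.sum(axis=1, keepdims=True)

    conditionals, num_conditionals = {}, {}
    for j in ordinal:
        for k in ordinal:
            if k.name == j.name:
                continue
            conditionals[(j.name, k.name)] = _cond(codes[j.name], j.levels,
                                                   codes[k.name], k.levels)
        for c in continuous:
            n_bins = int(codes[c.name].max()) + 1
            num_conditionals[(j.name, c.name)] = _cond(codes[j.name], j.levels,
                                                       codes[c.name], n_bins)

    names = [v.name for v in ordinal] + [v.name for v in continuous]
    nmi = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            val = _nmi_from_codes(codes[a], codes[b])
            nmi.loc[a, b] = nmi.loc[b, a] = val

    cov = chol = None
    if continuous:
        x = table.data[[v.name for v in continuous]].to_numpy(dtype=float)
        cov = np.atleast_2d(np.cov(x, rowvar=False))
        shrunk = (1.0 - lam) * cov + lam * np.diag(np.diag(cov))
        chol = np.linalg.cholesky(shrunk)

    return AttributeStats(
        feature_set=feature_set,
        ordinal_names=[v.name for v in ordinal],
        continuous_names=[v.name for v in continuous],
        levels=levels, marginals=marginals, midpoint_cdf=midpoint,
        conditionals=conditionals, num_conditionals=num_conditionals,
        nmi=nmi, cov=cov, lam=lam, bins=bins, _chol=chol,
    )


def midpoint_cdf_distance(j: str, a: int, b: int, stats: AttributeStats) -> float:
    """Intra-attribute level distance ``|F_mid(a) - F_mid(b)|`` in [0, 1]."""
    fm = stats.midpoint_cdf[j]
    if not (0 <= a < len(fm) and 0 <= b < len(fm)):
        raise ValueError(f"invalid level for {j!r}: {a}, {b}")
    return float(abs(fm[a] - fm[b]))


def ordinal_value_distance(j: str, a: int, b: int, stats: AttributeStats) -> float:
    """Level distance for ordinal variable *j* combining the intra term with
    NMI-weighted Jensen–Shannon context terms:

    ``d_j(a,b)^2 = delta(a,b)^2 + sum_k w_jk * JSD_n(P(.|a), P(.|b))``

    where ``JSD_n`` is JSD normalized by ``ln 2`` and
    ``w_jk = nmi(j,k) / sum_k' nmi(j,k')`` over all other variables in the
    feature set.
    """
    if j not in stats.marginals:
        raise ValueError(f"{j!r} is not a fitted ordinal variable")
    intra = midpoint_cdf_distance(j, a, b, stats)
    total = intra * intra
    contexts = [k for k in stats.context_names if k != j]
    if contexts:
        weights = np.array([stats.nmi.loc[j, k] for k in contexts], dtype=float)
        wsum = weights.sum()
        if wsum > 0:
            weights /= wsum
            for w, k in zip(weights, contexts):
                if w == 0:
                    continue
                tab = (stats.conditionals[(j, k)] if k in stats.levels
                       else stats.num_conditionals[(j, k)])
                phi2 = jensen_shannon_divergence(tab[a], tab[b]) / np.log(2)
                total += w * phi2
    return float(np.sqrt(total))


def numeric_block_distance(x: np.ndarray, y: np.ndarray, stats: AttributeStats) -> float:
    """Shrinkage-Mahalanobis distance between two continuous sub-records."""
    if stats._chol is None:
        raise ValueError("stats were fitted without continuous variables")
    diff = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    z = np.linalg.solve(stats._chol, diff)
    return float(np.sqrt(z @ z))


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise record distances, zero diagonal."""

    ids: list
    d: np.ndarray

    def __post_init__(self) -> None:
        d = self.d
        if d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(d)) or (d < 0).any():
            raise ValueError("distances must be finite and non-negative")
        if np.abs(d - d.T).max() > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(d)).max() != 0:
            raise ValueError("diagonal must be exactly zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.d, index=self.ids, columns=self.ids).to_csv(path)


def _value_distance_tables(stats: AttributeStats) -> dict[str, np.ndarray]:
    tables = {}
    for j, lv in stats.levels.items():
        t = np.zeros((lv, lv))
        for a in range(lv):
            for b in range(a + 1, lv):
                t[a, b] = t[b, a] = ordinal_value_distance(j, a, b, stats)
        tables[j] = t
    return tables


def pairwise_distances(table: CohortTable, feature_set: str = "gi_only",
                       lam: float = 0.1, bins: int = 8,
                       stats: AttributeStats | None = None) -> DistanceMatrix:
    """Full pairwise distance matrix over the requested feature set.

    ``D^2 = s_ord * sum_j d_j(x_j, y_j)^2 + s_num * d_mahal(x, y)^2`` with
    the block scales chosen so each block's mean squared off-diagonal
    contribution equals its fraction of the attribute count.
    """
    if table.n_records < 3:
        raise ValueError("need at least 3 records")
    if stats is None:
        stats = fit_attribute_stats(table, feature_set, lam=lam, bins=bins)
    n = table.n_records
    n_ord, n_num = len(stats.ordinal_names), len(stats.continuous_names)
    n_attr = n_ord + n_num

    off = ~np.eye(n, dtype=bool)
    d2 = np.zeros((n, n))
    if n_ord:
        tables = _value_distance_tables(stats)
        a2 = np.zeros((n, n))
        for j in stats.ordinal_names:
            codes = table.data[j].to_numpy(dtype=np.int64)
            tj2 = tables[j] ** 2
            a2 += tj2[codes[:, None], codes[None, :]]
        mean_a = a2[off].mean()
        if mean_a > 0:
            d2 += (n_ord / n_attr) / mean_a * a2
    if n_num:
        x = table.data[stats.continuous_names].to_numpy(dtype=float)
        z = np.linalg.solve(stats._chol, x.T).T  # whiten: rows z with |z_i-z_j| = mahal
        b2 = cdist(z, z, metric="sqeuclidean")
        mean_b = b2[off].mean()
        if mean_b > 0:
            d2 += (n_num / n_attr) / mean_b * b2

    d2 = 0.5 * (d2 + d2.T)
    np.fill_diagonal(d2, 0.0)
    d = np.sqrt(np.maximum(d2, 0.0))
    return DistanceMatrix(ids=table.record_ids, d=d)
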
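"""Cluster symptom profiles and their statistical characterization.

A cluster's profile is the vector of z-values per variable — the cluster
mean minus the population mean, in population standard deviations — the
quantity a radar plot displays.  A variable counts as *high* in a cluster
when its z exceeds 0.5, or when a cluster-vs-rest Mann–Whitney test gives
p < 0.001 with effect size r > 0.3; it is *low* at or below the radar
baseline (z <= 0) and *moderate* in between.  Across clusters,
Kruskal–Wallis with Conover–Iman post-hoc comparisons and Holm correction
summarizes which variables separate the clusters.

Ordinal Likert codes are treated as numeric scores throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort_io import CohortTable


@dataclass(frozen=True)
class LevelRuleConfig:
    """Thresholds for the high/moderate/low triage of a variable."""

    z_high: float = 0.5
    p_high: float = 0.001
    r_high: float = 0.3
    z_low: float = 0.0

    def __post_init__(self) -> None:
        if not self.z_low < self.z_high:
            raise ValueError("z_low must be below z_high")
        if not 0 < self.p_high < 1:
            raise ValueError("p_high must be in (0, 1)")


def z_profile(table: CohortTable, labels: np.ndarray, cluster: int,
              variables: list[str] | None = None) -> pd.Series:
    """(cluster mean - population mean) / population SD, per variable."""
    variables = variables or table.schema.names
    mask = np.asarray(labels) == cluster
    if not mask.any():
        raise ValueError(f"cluster {cluster} is empty")
    data = table.data[variables].astype(float)
    sd = data.std(ddof=1)
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise ValueError(f"zero-variance variables: {zero}")
    return (data[mask].mean() - data.mean()) / sd


def mwu_vs_rest(table: CohortTable, labels: np.ndarray, cluster: int,
                variable: str) -> tuple[float, float, float]:
    """Two-sided Mann–Whitney U of cluster vs the rest for one variable.

    Uses the tie-corrected normal approximation (no continuity
    correction); returns ``(U, p, r)`` with effect size ``r = |Z|/sqrt(N)``.
    """
    mask = np.asarray(labels) == cluster
    x = table.data.loc[mask, variable].to_numpy(dtype=float)
    y = table.data.loc[~mask, variable].to_numpy(dtype=float)
    return _mwu(x, y)


def _mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    n = n1 + n2
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:  # all values tied
        return float(u), 1.0, 0.0
    z = (u - n1 * n2 / 2.0) / np.sqrt(var_u)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(u), float(min(p, 1.0)), float(abs(z) / np.sqrt(n))


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square p (df = g-1).

    Degenerate all-identical input returns (0, 1) rather than raising.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def conover_posthoc(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Conover–Iman pairwise t statistics on rank means after
    Kruskal–Wallis, with the pooled tie-corrected variance.

    ``t_ij = (Rbar_i - Rbar_j) / sqrt(S^2 (n-1-H)/(n-g) (1/n_i + 1/n_j))``
    with ``S^2 = (sum R^2 - n (n+1)^2 / 4) / (n - 1)``; two-sided p from
    Student's t with n - g degrees of freedom.  Returns (statistics,
    raw p) as g x g matrices with zero diagonal / unit diagonal p.
    """
    g = len(groups)
    sizes = np.array([len(grp) for grp in groups])
    n = int(sizes.sum())
    if n - g <= 0:
        raise ValueError("need n - g > 0 residual degrees of freedom")
    pooled = np.concatenate([np.asarray(grp, dtype=float) for grp in groups])
    ranks = sps.rankdata(pooled)
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    rbar = np.array([s.mean() for s in split])
    h, _ = kruskal_wallis(groups)
    s2 = (np.sum(ranks ** 2) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    factor = s2 * max(n - 1 - h, 0.0) / (n - g)

    stat = np.zeros((g, g))
    pval = np.ones((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            se2 = factor * (1.0 / sizes[i] + 1.0 / sizes[j])
            if se2 <= 0:
                t = np.inf * np.sign(rbar[i] - rbar[j]) if rbar[i] != rbar[j] else 0.0
            else:
                t = (rbar[i] - rbar[j]) / np.sqrt(se2)
            p = 2.0 * sps.t.sf(abs(t), df=n - g) if np.isfinite(t) else 0.0
            if t == 0.0:
                p = 1.0
            stat[i, j], stat[j, i] = t, -t
            pval[i, j] = pval[j, i] = min(p, 1.0)
    return stat, pval


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(
        np.maximum.accumulate(p[order] * (m - np.arange(m))), 1.0
    )
    return adjusted


def classify_levels(z: pd.Series, p: pd.Series, r: pd.Series,
                    rule: LevelRuleConfig = LevelRuleConfig()) -> pd.Series:
    """Per-variable high/moderate/low level from z, p and effect size.

    The significance branch requires an upward deviation (z above the
    radar baseline): the Mann–Whitney effect size is sign-blind, and a
    symptom sitting significantly *below* the population mean is low, not
    high.
    """
    high = (z > rule.z_high) | (
        (z > rule.z_low) & (p < rule.p_high) & (r > rule.r_high)
    )
    low = (~high) & (z <= rule.z_low)
    out = pd.Series("moderate", index=z.index)
    out[high] = "high"
    out[low] = "low"
    return out


@dataclass
class ClusterProfile:
    """Everything the radar plot and the supplementary tables carry for
    one cluster: z-values, cluster-vs-rest tests, and levels."""

    cluster: int
    size: int
    variables: list[str]
    z: pd.Series
    mwu_u: pd.Series
    mwu_p: pd.Series
    holm_p: pd.Series
    effect_r: pd.Series
    level: pd.Series

    def n_high(self, variables: list[str] | None = None) -> int:
        lv = self.level if variables is None else self.level[variables]
        return int((lv == "high").sum())

    def to_dict(self) -> dict:
        return {
            "cluster": int(self.cluster),
            "size": int(self.size),
            "variables": list(self.variables),
            "z": {k: float(v) for k, v in self.z.items()},
            "mwu_u": {k: float(v) for k, v in self.mwu_u.items()},
            "mwu_p": {k: float(v) for k, v in self.mwu_p.items()},
            "holm_p": {k: float(v) for k, v in self.holm_p.items()},
            "effect_r": {k: float(v) for k, v in self.effect_r.items()},
            "level": {k: str(v) for k, v in self.level.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterProfile":
        variables = list(d["variables"])
        def ser(key):
            return pd.Series({k: d[key][k] for k in variables})
        return cls(
            cluster=d["cluster"], size=d["size"], variables=variables,
            z=ser("z"), mwu_u=ser("mwu_u"), mwu_p=ser("mwu_p"),
            holm_p=ser("holm_p"), effect_r=ser("effect_r"),
            level=pd.Series({k: d["level"][k] for k in variables}),
        )


def build_cluster_profiles(table: CohortTable, labels: np.ndarray, k: int,
                           variables: list[str] | None = None,
                           rule: LevelRuleConfig = LevelRuleConfig()
                           ) -> list[ClusterProfile]:
    """Profile every cluster: z-values, MWU vs rest (Holm-corrected across
    variables within the cluster), effect sizes, and levels."""
    variables = variables or table.schema.names
    labels = np.asarray(labels)
    profiles = []
    for c in range(k):
        z = z_profile(table, labels, c, variables)
        u = pd.Series(0.0, index=variables)
        p = pd.Series(1.0, index=variables)
        r = pd.Series(0.0, index=variables)
        for v in variables:
            u[v], p[v], r[v] = mwu_vs_rest(table, labels, c, v)
        hp = pd.Series(holm_adjust(p.to_numpy()), index=variables)
        level = classify_levels(z, p, r, rule)
        profiles.append(ClusterProfile(
            cluster=c, size=int((labels == c).sum()), variables=list(variables),
            z=z, mwu_u=u, mwu_p=p, holm_p=hp, effect_r=r, level=level,
        ))
    return profiles


def kruskal_conover_table(table: CohortTable, labels: np.ndarray, k: int,
                          variables: list[str] | None = None) -> dict:
    """Per-variable multi-group summary across clusters: Kruskal–Wallis H
    and p (Holm-corrected across variables) plus the Conover–Iman pairwise
    Holm-adjusted p matrix."""
    variables = variables or table.schema.names
    labels = np.asarray(labels)
    groups_by_var = {
        v: [table.data.loc[labels == c, v].to_numpy(dtype=float) for c in range(k)]
        for v in variables
    }
    h_vals, p_vals, conover = [], [], {}
    for v in variables:
        h, p = kruskal_wallis(groups_by_var[v])
        h_vals.append(h)
        p_vals.append(p)
        _, raw = conover_posthoc(groups_by_var[v])
        iu = np.triu_indices(k, 1)
        adj = holm_adjust(raw[iu])
        mat = np.ones((k, k))
        mat[iu] = adj
        mat.T[iu] = adj
        conover[v] = mat.tolist()
    holm_p = holm_adjust(np.array(p_vals))
    return {
        "variables": list(variables),
        "H": [float(h) for h in h_vals],
        "p": [float(p) for p in p_vals],
        "holm_p": [float(p) for p in holm_p],
        "conover_holm_p": conover,
    }
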
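"""Two-phase clustering: GI-only subtyping, purity triage, re-clustering.

Phase one clusters the cohort on the 30 GI symptoms alone, chooses k by
S-Dbw, and profiles every cluster.  Clusters dominated by a handful of
related symptoms (at most ``purity_max_high`` GI variables at level
"high") are *pure*: they correspond to single syndromes and are reported
as-is.  The remaining *non-pure* clusters — many elevated symptoms, the
overlap phenotype — are pooled and re-clustered in phase two on GI
symptoms plus the psychological scores, where their members separate by
psychological burden into overlapped clusters (OCs).

All randomness flows from one master seed through named child seeds
(`selection_stability.child_seed`), so each stage is independently
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import CohortTable, read_inputs, write_outputs
from .profile_stats import (ClusterProfile, LevelRuleConfig,
                            build_cluster_profiles, kruskal_conover_table)
from .selection_stability import (DEFAULT_CA_THRESHOLD, DEFAULT_RATES,
                                  DEFAULT_REPS, SdbwCurve, SelectionResult,
                                  StabilityReport, child_seed,
                                  select_and_cluster, stability_analysis)
from .spectral_clustering import DEFAULT_NEIGHBOR, ClusteringResult

logger = logging.getLogger("fgidclust")


@dataclass
class PipelineConfig:
    k_min: int = 2
    k_max: int = 15
    seed: int = 0
    level_rule: LevelRuleConfig = field(default_factory=LevelRuleConfig)
    purity_max_high: int = 3
    stability: bool = False
    stability_threshold: float = DEFAULT_CA_THRESHOLD
    rates: tuple = DEFAULT_RATES
    reps: int = DEFAULT_REPS
    subsample_mode: str = "removed"
    lam: float = 0.1
    bins: int = 8
    neighbor_m: int = DEFAULT_NEIGHBOR

    def __post_init__(self) -> None:
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.purity_max_high < 1:
            raise ValueError("purity_max_high must be >= 1")

    def k_range(self, n: int) -> range:
        """k range clipped so k_max never exceeds n/2."""
        hi = min(self.k_max, n // 2)
        if hi < self.k_min:
            raise ValueError(f"too few records ({n}) for k_min={self.k_min}")
        return range(self.k_min, hi + 1)


@dataclass
class StepResult:
    clustering: ClusteringResult
    curve: SdbwCurve
    profiles: list[ClusterProfile]
    kw_table: dict
    purity: dict[int, str] | None = None
    stability: StabilityReport | None = None


@dataclass
class PipelineResult:
    step1: StepResult
    step2: StepResult | None
    final_assignment: pd.DataFrame  # record_id, step, cluster_label, source_purity


def classify_purity(profile: ClusterProfile, compactness: float,
                    config: PipelineConfig) -> str:
    """Pure iff at most ``purity_max_high`` GI variables are "high".

    ``compactness`` is reported alongside for audit but does not gate.
    """
    del compactness
    return "non_pure" if profile.n_high() > config.purity_max_high else "pure"


def run_step_one(table: CohortTable, config: PipelineConfig) -> StepResult:
    """GI-only clustering with S-Dbw selection, profiling and purity flags.

    Psychological columns are never touched: the feature set restricts to
    the upper/lower-GI ordinal block.
    """
    gi_vars = [v.name for v in table.schema.subset("gi_only")]
    seed1 = child_seed(config.seed, "step1")
    sel = select_and_cluster(table, "gi_only", config.k_range(table.n_records),
                             seed=seed1, lam=config.lam, bins=config.bins,
                             m=config.neighbor_m)
    logger.info("step 1: selected k=%d over %s", sel.k_star, list(sel.curve.k_values))
    profiles = build_cluster_profiles(table, sel.result.labels, sel.k_star,
                                      variables=gi_vars, rule=config.level_rule)
    purity = {
        p.cluster: classify_purity(p, float(sel.result.compactness[p.cluster]), config)
        for p in profiles
    }
    logger.info("step 1 purity: %s", purity)
    kw = kruskal_conover_table(table, sel.result.labels, sel.k_star, gi_vars)
    stability = None
    if config.stability:
        stability = stability_analysis(
            table, "gi_only", k_range=[sel.k_star], rates=config.rates,
            reps=config.reps, seed=child_seed(config.seed, "stability1"),
            threshold=config.stability_threshold, selected_k=sel.k_star,
            mode=config.subsample_mode, lam=config.lam, bins=config.bins,
            m=config.neighbor_m)
    return StepResult(sel.result, sel.curve, profiles, kw, purity, stability)


def run_step_two(table: CohortTable, step1: StepResult,
                 config: PipelineConfig) -> StepResult | None:
    """Re-cluster the pooled non-pure members on GI + psychological scores.

    Distance statistics are refit on the subpopulation.  Returns ``None``
    when step one produced no non-pure cluster.
    """
    nonpure = [c for c, flag in step1.purity.items() if flag == "non_pure"]
    if not nonpure:
        logger.info("step 2: no non-pure clusters; nothing to re-cluster")
        return None
    mask = np.isin(step1.clustering.labels, nonpure)
    ids = [rid for rid, keep in zip(step1.clustering.ids, mask) if keep]
    if len(ids) < 2 * config.k_min:
        raise ValueError(
            f"non-pure pool has {len(ids)} members; need >= {2 * config.k_min}")
    sub = table.subset_records(ids)
    seed2 = child_seed(config.seed, "step2")
    sel = select_and_cluster(sub, "gi_plus_psych", config.k_range(sub.n_records),
                             seed=seed2, lam=config.lam, bins=config.bins,
                             m=config.neighbor_m)
    logger.info("step 2: %d records, selected k=%d", sub.n_records, sel.k_star)
    profiles = build_cluster_profiles(sub, sel.result.labels, sel.k_star,
                                      rule=config.level_rule)
    kw = kruskal_conover_table(sub, sel.result.labels, sel.k_star)
    stability = None
    if config.stability:
        stability = stability_analysis(
            sub, "gi_plus_psych", k_range=[sel.k_star], rates=config.rates,
            reps=config.reps, seed=child_seed(config.seed, "stability2"),
            threshold=config.stability_threshold, selected_k=sel.k_star,
            mode=config.subsample_mode, lam=config.lam, bins=config.bins,
            m=config.neighbor_m)
    return StepResult(sel.result, sel.curve, profiles, kw, None, stability)


def _final_assignment(table: CohortTable, step1: StepResult,
                      step2: StepResult | None) -> pd.DataFrame:
    step2_label = {}
    if step2 is not None:
        step2_label = dict(zip(step2.clustering.ids, step2.clustering.labels))
    rows = []
    for rid, c1 in zip(step1.clustering.ids, step1.clustering.labels):
        purity = step1.purity[int(c1)]
        if purity == "pure" or rid not in step2_label:
            rows.append((rid, "step1", int(c1), purity))
        else:
            rows.append((rid, "step2", int(step2_label[rid]), purity))
    return pd.DataFrame(rows, columns=["record_id", "step", "cluster_label",
                                       "source_purity"])


def run_pipeline_table(table: CohortTable, config: PipelineConfig,
                       out_dir: str | Path | None = None) -> PipelineResult:
    """Run both phases on an in-memory cohort table."""
    step1 = run_step_one(table, config)
    step2 = run_step_two(table, step1, config)
    result = PipelineResult(step1, step2, _final_assignment(table, step1, step2))
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def run_pipeline(schema_path: str | Path, cohort_path: str | Path,
                 config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Read + validate inputs, run both phases, optionally write outputs.

    Deterministic given ``config.seed``: two runs with the same seed write
    byte-identical files.
    """
    config = config or PipelineConfig()
    _, table = read_inputs(schema_path, cohort_path)
    return run_pipeline_table(table, config, out_dir)
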
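"""Synthetic questionnaire cohorts with planted symptom archetypes.

The generator emulates the statistical structure the two-step analysis
assumes: "pure" archetypes elevate one to three related GI symptoms on the
4-point Likert scale, while "non-pure" archetypes elevate a broad set of
symptoms and differ from each other chiefly in psychological burden
(anxiety, depression, distress, neuroticism).  Each ordinal cell is an
independent categorical draw from the archetype's elevated or baseline
level distribution; each psychological score is a normal draw rounded to an
integer total and clipped to the questionnaire range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import CohortTable, Variable, VariableSchema

LIKERT_LEVELS = 4
# generator defaults: baseline vs elevated Likert response profiles
BASELINE_DIST = (0.55, 0.30, 0.10, 0.05)
ELEVATED_DIST = (0.05, 0.15, 0.35, 0.45)

UPPER_GI = (
    "heartburn", "acid_regurgitation", "chest_pain", "dysphagia", "globus",
    "belching", "nausea", "vomiting", "rumination", "early_satiety",
    "postprandial_fullness", "epigastric_pain", "epigastric_burning",
    "bitter_taste", "retrosternal_discomfort",
)
LOWER_GI = (
    "abdominal_pain", "pain_relief_by_defecation", "bloating",
    "abdominal_distension", "hard_stool", "infrequent_stool", "straining",
    "incomplete_evacuation", "anorectal_blockage", "manual_maneuvers",
    "loose_stool", "frequent_stool", "urgency", "fecal_incontinence",
    "mucus_passage",
)
PSYCH_RANGES = {
    "hads_anxiety": (0.0, 21.0),
    "hads_depression": (0.0, 21.0),
    "ghq12": (0.0, 12.0),
    "neo_neuroticism": (0.0, 48.0),
    "neo_extraversion": (0.0, 48.0),
    "neo_openness": (0.0, 48.0),
    "neo_agreeableness": (0.0, 48.0),
    "neo_conscientiousness": (0.0, 48.0),
}

# psychological burden presets: mean scores per burden grade; the remaining
# NEO factors are burden-independent (mean 24, sd 6)
_BURDEN_MEANS = {
    "low": {"hads_anxiety": 4.0, "hads_depression": 4.0, "ghq12": 2.0, "neo_neuroticism": 16.0},
    "moderate": {"hads_anxiety": 8.0, "hads_depression": 8.0, "ghq12": 5.0, "neo_neuroticism": 24.0},
    "high": {"hads_anxiety": 12.0, "hads_depression": 12.0, "ghq12": 8.0, "neo_neuroticism": 32.0},
}
_NEUTRAL_NEO = ("neo_extraversion", "neo_openness", "neo_agreeableness", "neo_conscientiousness")
_SD = {"hads_anxiety": 3.0, "hads_depression": 3.0, "ghq12": 3.0}  # NEO factors: 6.0


def default_schema() -> VariableSchema:
    """38-variable schema: 30 four-level GI symptoms + 8 psychological scores."""
    variables = [
        Variable(name=n, vtype="ordinal", group="upper_gi", levels=LIKERT_LEVELS)
        for n in UPPER_GI
    ]
    variables += [
        Variable(name=n, vtype="ordinal", group="lower_gi", levels=LIKERT_LEVELS)
        for n in LOWER_GI
    ]
    variables += [
        Variable(name=n, vtype="continuous", group="psych", vrange=rng)
        for n, rng in PSYCH_RANGES.items()
    ]
    return VariableSchema(tuple(variables))


@dataclass(frozen=True)
class ClusterArchetype:
    """One planted cluster: which GI symptoms are elevated and how burdened
    the psychological profile is."""

    name: str
    n_records: int
    elevated_gi: frozenset[str]
    gi_elevated_dist: tuple[float, ...] = ELEVATED_DIST
    gi_baseline_dist: tuple[float, ...] = BASELINE_DIST
    psych_burden: str = "low"
    psych_means: dict = field(default_factory=dict)
    psych_sds: dict = field(default_factory=dict)
    is_pure_truth: bool = True

    def __post_init__(self) -> None:
        for dist in (self.gi_elevated_dist, self.gi_baseline_dist):
            arr = np.asarray(dist, dtype=float)
            if arr.min() < 0 or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: level distribution must be a probability vector")
        if self.psych_burden not in _BURDEN_MEANS:
            raise ValueError(f"{self.name}: unknown psych burden {self.psych_burden!r}")
        if self.n_records < 1:
            raise ValueError(f"{self.name}: n_records must be positive")


def _burden_params(burden: str) -> tuple[dict, dict]:
    means = dict(_BURDEN_MEANS[burden])
    for n in _NEUTRAL_NEO:
        means[n] = 24.0
    sds = {n: _SD.get(n, 6.0) for n in PSYCH_RANGES}
    return means, sds


@dataclass(frozen=True)
class CohortSpec:
    archetypes: tuple[ClusterArchetype, ...]
    schema: VariableSchema
    seed: int

    def __post_init__(self) -> None:
        total = sum(a.n_records for a in self.archetypes)
        if total < 10 * len(self.archetypes):
            raise ValueError("need at least 10 records per archetype on average")
        gi_names = {v.name for v in self.schema.subset("gi_only")}
        for a in self.archetypes:
            stray = set(a.elevated_gi) - gi_names
            if stray:
                raise ValueError(f"{a.name}: elevated_gi not in schema GI variables: {sorted(stray)}")


# broad symptom set shared by the three non-pure archetypes
_NONPURE_ELEVATED = frozenset({
    "heartburn", "chest_pain", "belching", "nausea", "postprandial_fullness",
    "epigastric_pain", "abdominal_pain", "bloating", "abdominal_distension",
    "urgency",
})

_PURE_ELEVATED = {
    "reflux": frozenset({"heartburn", "acid_regurgitation"}),
    "dyspepsia": frozenset({"postprandial_fullness", "early_satiety", "epigastric_pain"}),
    "constipation": frozenset({"hard_stool", "infrequent_stool", "straining"}),
    "diarrhea": frozenset({"loose_stool", "frequent_stool", "urgency"}),
}


def default_archetypes(n_per_cluster: int, seed: int = 0) -> CohortSpec:
    """Miniature study design: 4 pure + 3 non-pure planted clusters.

    Pure archetypes elevate 2–3 related symptoms each at low psychological
    burden; the non-pure trio shares one broad 10-symptom elevation set and
    differs only in psychological burden (low / moderate / high).
    """
    if n_per_cluster < 20:
        raise ValueError("n_per_cluster must be >= 20")
    schema = default_schema()
    archetypes = []
    for name, elev in _PURE_ELEVATED.items():
        means, sds = _burden_params("low")
        archetypes.append(ClusterArchetype(
            name=f"pure_{name}", n_records=n_per_cluster, elevated_gi=elev,
            psych_burden="low", psych_means=means, psych_sds=sds,
            is_pure_truth=True,
        ))
    for burden in ("low", "moderate", "high"):
        means, sds = _burden_params(burden)
        archetypes.append(ClusterArchetype(
            name=f"nonpure_{burden}", n_records=n_per_cluster,
            elevated_gi=_NONPURE_ELEVATED, psych_burden=burden,
            psych_means=means, psych_sds=sds, is_pure_truth=False,
        ))
    return CohortSpec(tuple(archetypes), schema, seed)


def generate_cohort(spec: CohortSpec) -> tuple[CohortTable, pd.Series]:
    """Draw a cohort; returns the table and per-record truth labels.

    Deterministic given ``spec.seed``; records are emitted archetype by
    archetype with ids ``r0000, r0001, ...``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    labels = []
    for arch in spec.archetypes:
        n = arch.n_records
        block: dict[str, np.ndarray] = {}
        for var in spec.schema.variables:
            if var.vtype == "ordinal":
                dist = (arch.gi_elevated_dist if var.name in arch.elevated_gi
                        else arch.gi_baseline_dist)
                block[var.name] = rng.choice(len(dist), size=n, p=np.asarray(dist))
            else:
                mean = arch.psych_means.get(var.name, 0.5 * sum(var.vrange))
                sd = arch.psych_sds.get(var.name, 1.0)
                draws = np.rint(rng.normal(mean, sd, size=n))
                block[var.name] = np.clip(draws, var.vrange[0], var.vrange[1])
        rows.append(pd.DataFrame(block))
        labels.extend([arch.name] * n)
    data = pd.concat(rows, ignore_index=True)
    data.index = pd.Index([f"r{i:04d}" for i in range(len(data))], name="record_id")
    truth = pd.Series(labels, index=data.index, name="truth")
    return CohortTable(data, spec.schema), truth
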
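import numpy as np
import pandas as pd
import pytest

from fgidclust import (CohortSpec, CohortTable, PipelineConfig, Variable,
                       VariableSchema, default_archetypes, generate_cohort,
                       run_pipeline_table)
from fgidclust.synthetic_cohort import (ClusterArchetype, _burden_params,
                                        default_schema, LOWER_GI, UPPER_GI,
                                        _NONPURE_ELEVATED)


@pytest.fixture
def tiny_schema():
    return VariableSchema((
        Variable(name="bloating", vtype="ordinal", group="lower_gi", levels=4),
        Variable(name="nausea", vtype="ordinal", group="upper_gi", levels=4),
        Variable(name="anxiety", vtype="continuous", group="psych", vrange=(0.0, 21.0)),
    ))


@pytest.fixture
def tiny_table(tiny_schema):
    data = pd.DataFrame(
        {"bloating": [0, 1, 2, 3, 1], "nausea": [1, 1, 0, 2, 3],
         "anxiety": [3.0, 5.0, 8.0, 12.0, 7.0]},
        index=pd.Index([f"p{i}" for i in range(5)], name="record_id"),
    )
    return CohortTable(data, tiny_schema)


def random_cohort(n=40, seed=0):
    """Small unstructured cohort (single baseline archetype split in two
    name-only groups) for metric property checks."""
    schema = default_schema()
    means, sds = _burden_params("low")
    archs = tuple(
        ClusterArchetype(name=f"g{i}", n_records=n // 2, elevated_gi=frozenset(),
                         psych_means=means, psych_sds=sds)
        for i in range(2)
    )
    table, _ = generate_cohort(CohortSpec(archs, schema, seed))
    return table


@pytest.fixture
def flat_cohort():
    return random_cohort(n=40, seed=3)


def sharp_cohort(n_per=60, seed=0, k=3):
    """Cohort with near-deterministic Likert responses: k planted clusters
    separated far beyond the noise floor."""
    schema = default_schema()
    sharp_lo = (0.94, 0.02, 0.02, 0.02)
    sharp_hi = (0.02, 0.02, 0.02, 0.94)
    gi = list(UPPER_GI + LOWER_GI)
    sets = [frozenset(gi[10 * i:10 * (i + 1)]) for i in range(k)]
    means, sds = _burden_params("low")
    archs = tuple(
        ClusterArchetype(name=f"s{i}", n_records=n_per, elevated_gi=s,
                         gi_elevated_dist=sharp_hi, gi_baseline_dist=sharp_lo,
                         psych_means=means, psych_sds=sds)
        for i, s in enumerate(sets)
    )
    return generate_cohort(CohortSpec(archs, schema, seed))


@pytest.fixture(scope="session")
def study_cohort():
    """The default study-scale cohort: 7 planted archetypes x 150 records."""
    spec = default_archetypes(150, seed=0)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def study_pipeline(study_cohort):
    table, _ = study_cohort
    return run_pipeline_table(table, PipelineConfig(seed=0))
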
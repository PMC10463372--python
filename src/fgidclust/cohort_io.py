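"""Cohort tables, variable schemas, and pipeline output files.

A cohort is a record-by-variable table of questionnaire summaries: ordinal
symptom items coded ``0..levels-1`` (Likert) and continuous psychological
scores (HADS, GHQ-12, NEO factors).  The schema declares, per variable, its
type, its admissible values, and whether it belongs to the upper-GI,
lower-GI, or psychological block.  Missing cells are rejected outright —
there is no imputation path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .two_step_pipeline import PipelineResult

ORDINAL = "ordinal"
CONTINUOUS = "continuous"
GI_GROUPS = ("upper_gi", "lower_gi")
GROUPS = GI_GROUPS + ("psych",)


class SchemaError(ValueError):
    """Malformed variable schema."""


class CohortError(ValueError):
    """Cohort file or table violates its schema."""


@dataclass(frozen=True)
class Variable:
    """One schema entry.

    Parameters
    ----------
    name : str
        Unique variable name (CSV column header).
    vtype : {"ordinal", "continuous"}
    group : {"upper_gi", "lower_gi", "psych"}
    levels : int, optional
        Number of ordinal levels; codes run ``0..levels-1``.  Ordinal only.
    vrange : (float, float), optional
        Inclusive admissible range.  Continuous only.
    """

    name: str
    vtype: str
    group: str
    levels: int | None = None
    vrange: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("variable with empty name")
        if self.vtype not in (ORDINAL, CONTINUOUS):
            raise SchemaError(f"{self.name}: unknown vtype {self.vtype!r}")
        if self.group not in GROUPS:
            raise SchemaError(f"{self.name}: unknown group {self.group!r}")
        if self.vtype == ORDINAL:
            if self.levels is None or self.levels < 2:
                raise SchemaError(f"{self.name}: ordinal levels must be >= 2")
            if self.vrange is not None:
                raise SchemaError(f"{self.name}: ordinal variable with range")
        else:
            if self.vrange is None or not (self.vrange[0] < self.vrange[1]):
                raise SchemaError(f"{self.name}: continuous range must satisfy min < max")
            if self.levels is not None:
                raise SchemaError(f"{self.name}: continuous variable with levels")


@dataclass(frozen=True)
class VariableSchema:
    """Ordered collection of :class:`Variable` entries."""

    variables: tuple[Variable, ...]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate variable names: {dupes}")
        if not any(v.group in GI_GROUPS for v in self.variables):
            raise SchemaError("schema declares no GI-group variable")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def subset(self, feature_set: str) -> list[Variable]:
        """Variables participating in a feature set.

        ``gi_only`` keeps the upper/lower-GI blocks; ``gi_plus_psych`` keeps
        everything.
        """
        if feature_set == "gi_only":
            return [v for v in self.variables if v.group in GI_GROUPS]
        if feature_set == "gi_plus_psych":
            return list(self.variables)
        raise ValueError(f"unknown feature set {feature_set!r}")

    def to_dict(self) -> dict:
        out = []
        for v in self.variables:
            entry: dict = {"name": v.name, "vtype": v.vtype, "group": v.group}
            if v.vtype == ORDINAL:
                entry["levels"] = v.levels
            else:
                entry["range"] = [float(v.vrange[0]), float(v.vrange[1])]
            out.append(entry)
        return {"variables": out}

    @classmethod
    def from_dict(cls, payload: dict) -> "VariableSchema":
        if not isinstance(payload, dict) or "variables" not in payload:
            raise SchemaError("schema must be a mapping with a 'variables' key")
        entries = []
        for raw in payload["variables"]:
            unknown = set(raw) - {"name", "vtype", "group", "levels", "range"}
            if unknown:
                raise SchemaError(
                    f"{raw.get('name', '<unnamed>')}: unknown schema fields {sorted(unknown)}"
                )
            rng = raw.get("range")
            entries.append(
                Variable(
                    name=raw.get("name", ""),
                    vtype=raw.get("vtype", ""),
                    group=raw.get("group", ""),
                    levels=raw.get("levels"),
                    vrange=tuple(float(x) for x in rng) if rng is not None else None,
                )
            )
        return cls(tuple(entries))


@dataclass
class CohortTable:
    """Validated record-by-variable table.

    ``data`` is indexed by record id, with columns in schema order.
    Construction does not validate cell values; use :func:`validate_cohort`
    (or :func:`read_inputs`, which raises on the first violation).
    """

    data: pd.DataFrame
    schema: VariableSchema

    def __post_init__(self) -> None:
        missing = [n for n in self.schema.names if n not in self.data.columns]
        if missing:
            raise CohortError(f"cohort table is missing schema columns: {missing}")
        extra = [c for c in self.data.columns if c not in self.schema.names]
        if extra:
            raise CohortError(f"cohort table has unknown columns: {extra}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise CohortError(f"duplicate record ids: {dupes[:5]}")
        # enforce schema column order
        self.data = self.data.loc[:, self.schema.names]

    @property
    def record_ids(self) -> list:
        return list(self.data.index)

    @property
    def n_records(self) -> int:
        return len(self.data)

    def subset_records(self, ids: Sequence) -> "CohortTable":
        return CohortTable(self.data.loc[list(ids)].copy(), self.schema)


def validate_cohort(table: CohortTable) -> list[str]:
    """Return violation messages; empty means the table is valid.

    Each message names the record id, the variable, and the broken rule.
    Never raises.
    """
    violations: list[str] = []
    for var in table.schema.variables:
        col = table.data[var.name]
        nan_mask = col.isna()
        for rid in table.data.index[nan_mask]:
            violations.append(f"record {rid!r}, variable {var.name!r}: missing value")
        vals = col[~nan_mask]
        if var.vtype == ORDINAL:
            numeric = pd.to_numeric(vals, errors="coerce")
            bad = numeric.isna() | (numeric != np.floor(numeric)) | (numeric < 0) | (
                numeric > var.levels - 1
            )
            for rid in vals.index[bad]:
                violations.append(
                    f"record {rid!r}, variable {var.name!r}: value {col[rid]!r} "
                    f"not an integer in [0, {var.levels - 1}]"
                )
        else:
            numeric = pd.to_numeric(vals, errors="coerce")
            lo, hi = var.vrange
            bad = numeric.isna() | ~np.isfinite(numeric) | (numeric < lo) | (numeric > hi)
            for rid in vals.index[bad]:
                violations.append(
                    f"record {rid!r}, variable {var.name!r}: value {col[rid]!r} "
                    f"outside [{lo}, {hi}]"
                )
    return violations


# ---------------------------------------------------------------------------
# file readers / writers
# ---------------------------------------------------------------------------

def read_schema(path: str | Path) -> VariableSchema:
    """Read a schema from YAML (``.yaml``/``.yml``) or JSON."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        payload = json.loads(text)
    else:
        payload = yaml.safe_load(text)
    return VariableSchema.from_dict(payload)


def write_schema(schema: VariableSchema, path: str | Path) -> None:
    path = Path(path)
    payload = schema.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


def read_cohort(path: str | Path, schema: VariableSchema) -> CohortTable:
    df = pd.read_csv(path)
    if "record_id" not in df.columns:
        raise CohortError("cohort CSV must have a 'record_id' first column")
    df = df.set_index("record_id")
    table = CohortTable(df, schema)
    violations = validate_cohort(table)
    if violations:
        head = "; ".join(violations[:5])
        more = f" (+{len(violations) - 5} more)" if len(violations) > 5 else ""
        raise CohortError(f"invalid cohort: {head}{more}")
    return table


def write_cohort(table: CohortTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="record_id")


def read_inputs(schema_path: str | Path, cohort_path: str | Path) -> tuple[VariableSchema, CohortTable]:
    """Read and validate a schema file plus its cohort CSV."""
    schema = read_schema(schema_path)
    return schema, read_cohort(cohort_path, schema)


def write_outputs(result: "PipelineResult", out_dir: str | Path) -> dict:
    """Write every pipeline artifact to ``out_dir`` and return the manifest.

    Files: ``labels.csv`` (final per-record assignment), ``sdbw_step1.csv``
    and ``sdbw_step2.csv`` (validity curves), ``stability.json``,
    ``profiles.json``, ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    result.final_assignment.to_csv(out_dir / "labels.csv", index=False)
    written.append("labels.csv")

    for step_name, step in (("step1", result.step1), ("step2", result.step2)):
        fname = f"sdbw_{step_name}.csv"
        if step is not None and step.curve is not None:
            step.curve.to_frame().to_csv(out_dir / fname, index=False)
        else:
            pd.DataFrame(columns=["k", "scatter", "density", "index"]).to_csv(
                out_dir / fname, index=False
            )
        written.append(fname)

    stability = {
        "step1": result.step1.stability.to_dict() if result.step1 and result.step1.stability else None,
        "step2": result.step2.stability.to_dict() if result.step2 and result.step2.stability else None,
    }
    (out_dir / "stability.json").write_text(json.dumps(stability, indent=1), encoding="utf-8")
    written.append("stability.json")

    profiles = {
        "step1": [p.to_dict() for p in (result.step1.profiles if result.step1 else [])],
        "step2": [p.to_dict() for p in (result.step2.profiles if result.step2 else [])],
        "kruskal_wallis": {
            "step1": result.step1.kw_table if result.step1 else None,
            "step2": result.step2.kw_table if result.step2 else None,
        },
    }
    (out_dir / "profiles.json").write_text(json.dumps(profiles, indent=1), encoding="utf-8")
    written.append("profiles.json")

    manifest = {"files": written}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    written.append("manifest.json")
    return manifest
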
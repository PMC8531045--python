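"""Cohort data model: variable registry, CSV I/O, and derived-variable rules.

A cohort is a flat patient-level table (one row per patient) together with a
registry of :class:`VariableSpec` entries that type every column.  Binary
variables are strictly 0/1; continuous variables are real-valued with units
kept as registry metadata only (no conversion is ever performed).  Analysis
is complete-case: records missing the outcome or any candidate value are
dropped at read time and the exclusion count is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CohortParseError,
    CohortValidationError,
    ConfigurationError,
)

logger = logging.getLogger(__name__)

BINARY = "binary"
CONTINUOUS = "continuous"
KINDS = (BINARY, CONTINUOUS)
ROLES = ("outcome", "candidate", "auxiliary", "id")

OUTCOME_NAME = "delirium"


@dataclass(frozen=True)
class Dichotomization:
    """Clinical cutoff turning a continuous measure into a flag.

    direction "ge": flag = 1 iff value >= cutoff (e.g. age >= 75);
    direction "lt": flag = 1 iff value <  cutoff (e.g. SBP < 120 mmHg).
    """

    cutoff: float
    direction: str  # "ge" | "lt"

    def __post_init__(self):
        if self.direction not in ("ge", "lt"):
            raise ConfigurationError(
                f"dichotomization direction must be 'ge' or 'lt', got {self.direction!r}"
            )

    @property
    def flag_name_suffix(self) -> str:
        return f"_{self.direction}{self.cutoff:g}"


@dataclass(frozen=True)
class Derivation:
    """Rule producing a binary variable from existing columns.

    rule "any_of": logical OR over the listed binary source flags.
    rule "threshold_or_flag": 1 iff flag source == 1 OR measure source
    strictly exceeds ``threshold`` (e.g. suspected infection from the
    admission-reason flag and/or CRP > 5 mg/L).
    """

    rule: str  # "any_of" | "threshold_or_flag"
    sources: tuple[str, ...]
    threshold: Optional[float] = None

    def __post_init__(self):
        if self.rule not in ("any_of", "threshold_or_flag"):
            raise ConfigurationError(f"unknown derivation rule {self.rule!r}")
        if self.rule == "threshold_or_flag":
            if len(self.sources) != 2 or self.threshold is None:
                raise ConfigurationError(
                    "threshold_or_flag needs exactly (flag, measure) sources and a threshold"
                )


@dataclass(frozen=True)
class VariableSpec:
    """Typed description of one cohort column."""

    name: str
    kind: str = BINARY
    role: str = "candidate"
    unit: Optional[str] = None
    dichotomization: Optional[Dichotomization] = None
    derivation: Optional[Derivation] = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigurationError(f"variable {self.name!r}: unknown kind {self.kind!r}")
        if self.role not in ROLES:
            raise ConfigurationError(f"variable {self.name!r}: unknown role {self.role!r}")
        if self.dichotomization is not None and self.kind != CONTINUOUS:
            raise ConfigurationError(
                f"variable {self.name!r}: dichotomization only applies to continuous variables"
            )


def check_registry(registry: Sequence[VariableSpec]) -> None:
    """Enforce registry-level invariants (unique names, one binary outcome,
    derivation sources resolvable)."""
    names = [v.name for v in registry]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ConfigurationError(f"duplicate variable names in registry: {dup}")
    outcomes = [v for v in registry if v.role == "outcome"]
    if len(outcomes) != 1:
        raise ConfigurationError(
            f"registry must contain exactly one outcome variable, found {len(outcomes)}"
        )
    if outcomes[0].kind != BINARY:
        raise ConfigurationError("the outcome variable must be binary")
    known = set(names)
    for v in registry:
        if v.derivation is not None:
            missing = [s for s in v.derivation.sources if s not in known]
            if missing:
                raise ConfigurationError(
                    f"derivation for {v.name!r} references absent variables: {missing}"
                )


@dataclass
class Cohort:
    """Patient-level table plus its variable registry.

    ``data`` holds an ``id`` column followed by one column per registry
    variable.  Use :meth:`values` for numpy access to a single variable and
    :meth:`outcome` for the binary outcome vector.
    """

    data: pd.DataFrame
    registry: list[VariableSpec]
    label: str = ""
    provenance: str = ""

    def __post_init__(self):
        check_registry(self.registry)
        if "id" not in self.data.columns:
            raise CohortValidationError("cohort table must contain an 'id' column")
        if self.data["id"].duplicated().any():
            raise CohortValidationError("patient ids are not unique")
        missing_cols = [v.name for v in self.registry if v.name not in self.data.columns]
        if missing_cols:
            raise CohortValidationError(f"registry variables missing from table: {missing_cols}")
        for v in self.registry:
            if v.kind == BINARY:
                col = self.data[v.name]
                bad = col.dropna().loc[lambda s: ~s.isin([0, 1, 0.0, 1.0])]
                if len(bad):
                    raise CohortValidationError(
                        f"binary variable {v.name!r} contains non-0/1 value "
                        f"{bad.iloc[0]!r} (row index {bad.index[0]})"
                    )

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def outcome_name(self) -> str:
        return next(v.name for v in self.registry if v.role == "outcome")

    def spec(self, name: str) -> VariableSpec:
        for v in self.registry:
            if v.name == name:
                return v
        raise KeyError(name)

    def has_variable(self, name: str) -> bool:
        return any(v.name == name for v in self.registry)

    def values(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise KeyError(name)
        return self.data[name].to_numpy(dtype=float)

    def outcome(self) -> np.ndarray:
        return self.data[self.outcome_name].to_numpy(dtype=int)

    def candidate_names(self, kind: Optional[str] = None) -> list[str]:
        """Candidate-role variable names in registry order."""
        return [
            v.name
            for v in self.registry
            if v.role == "candidate" and (kind is None or v.kind == kind)
        ]

    def with_variable(self, spec: VariableSpec, values: np.ndarray) -> "Cohort":
        """Return a new cohort with one column added (or replaced)."""
        data = self.data.copy()
        data[spec.name] = values
        registry = [v for v in self.registry if v.name != spec.name] + [spec]
        # keep original registry order for replaced variables
        if any(v.name == spec.name for v in self.registry):
            registry = [spec if v.name == spec.name else v for v in self.registry]
        return Cohort(data, registry, label=self.label, provenance=self.provenance)

    def subset(self, mask: np.ndarray, label_suffix: str = "") -> "Cohort":
        data = self.data.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        return Cohort(
            data,
            list(self.registry),
            label=self.label + label_suffix,
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_cohort(path: str | Path, registry: Sequence[VariableSpec], label: str = "") -> Cohort:
    """Read a cohort CSV and apply the complete-case contract.

    The header must contain every registry variable whose role is not
    ``auxiliary``.  Binary columns accept only 0, 1 or empty; any other value
    raises :class:`CohortValidationError` naming the column and line.
    Records missing the outcome or any candidate value are dropped, with the
    exclusion count logged.
    """
    path = Path(path)
    if not path.exists():
        raise CohortParseError(f"cohort file not found: {path}")
    check_registry(registry)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as e:  # pandas messages name the offending line
        raise CohortParseError(f"malformed CSV {path}: {e}") from e
    df = df.mask(df == "")

    required = [v.name for v in registry if v.role != "auxiliary" and v.derivation is None]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: header missing required columns {missing}")

    out = pd.DataFrame()
    out["id"] = df["id"] if "id" in df.columns else np.arange(len(df)).astype(str)
    for v in registry:
        if v.name not in df.columns:
            if v.derivation is not None:
                continue  # derived later
            out[v.name] = np.nan
            continue
        raw = df[v.name]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = raw.notna() & numeric.isna()
        if v.kind == BINARY:
            bad |= raw.notna() & ~numeric.isin([0, 1])
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError(
                f"{path}: column {v.name!r}, line {i + 2}: "
                f"invalid {v.kind} value {raw.iloc[i]!r}"
            )
        out[v.name] = numeric
    for v in registry:
        if v.derivation is not None and v.name not in out.columns:
            out[v.name] = np.nan

    strict = [v.name for v in registry if v.role in ("outcome", "candidate") and v.derivation is None]
    complete = out[strict].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "read_cohort(%s): excluded %d of %d records with missing outcome/candidate values",
            path, n_dropped, len(out),
        )
    out = out.loc[complete].reset_index(drop=True)
    cohort = Cohort(out, list(registry), label=label or path.stem, provenance=str(path))
    # derived columns present in the file are recomputed for consistency
    rules = [v for v in registry if v.derivation is not None]
    if rules:
        cohort = derive_variables(cohort, rules)
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write ``id``, outcome, then the remaining registry variables as CSV.

    Binary values are written as bare 0/1, missing values as empty fields, so
    a write/read round trip reproduces the table exactly.
    """
    path = Path(path)
    cols = ["id", cohort.outcome_name] + [
        v.name for v in cohort.registry if v.role != "outcome"
    ]
    df = cohort.data[cols].copy()
    for v in cohort.registry:
        if v.kind == BINARY:
            df[v.name] = df[v.name].map(lambda x: "" if pd.isna(x) else str(int(x)))
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Derived variables
# ---------------------------------------------------------------------------

def derive_variables(cohort: Cohort, rules: Iterable[VariableSpec]) -> Cohort:
    """Append (or recompute) derived binary columns.

    ``any_of`` takes the logical OR over the listed binary source flags
    (missing treated as 0 only if every source is missing-free is not
    required; NaN propagates as 0 contribution but an all-missing row yields
    NaN).  ``threshold_or_flag`` is flag == 1 OR measure strictly greater
    than the threshold.  Applying the same rules twice is idempotent.
    """
    out = cohort
    for spec in rules:
        if spec.derivation is None:
            raise ConfigurationError(f"variable {spec.name!r} has no derivation rule")
        d = spec.derivation
        for s in d.sources:
            if s not in out.data.columns:
                raise ConfigurationError(
                    f"derivation for {spec.name!r} references absent variable {s!r}"
                )
        if d.rule == "any_of":
            src = out.data[list(d.sources)].to_numpy(dtype=float)
            vals = np.where(
                np.all(np.isnan(src), axis=1),
                np.nan,
                (np.nan_to_num(src) == 1).any(axis=1).astype(float),
            )
        else:  # threshold_or_flag
            flag = out.data[d.sources[0]].to_numpy(dtype=float)
            measure = out.data[d.sources[1]].to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                vals = (
                    (np.nan_to_num(flag) == 1) | (np.nan_to_num(measure, nan=-np.inf) > d.threshold)
                ).astype(float)
            vals = np.where(np.isnan(flag) & np.isnan(measure), np.nan, vals)
        out = out.with_variable(spec, vals)
    return out


# ---------------------------------------------------------------------------
# Default registry for ingested (file-based) cohorts
# ---------------------------------------------------------------------------

PSYCHOTROPIC_CLASSES = (
    "antiepileptics",
    "antipsychotics",
    "antidepressants_ssri_snri",
    "antidepressants_atypical",
    "antidepressants_tricyclic",
    "antidementia_drugs",
    "hypnotics",
    "opioids",
    "parkinson_drugs",
)


def default_registry() -> list[VariableSpec]:
    """Registry for ED observation-unit cohorts.

    Carries the clinical dichotomization cutoffs (age >= 75 y, SBP < 120
    mmHg, Na < 135 mEq/L, Hb < 10 g/dL) and the two derived flags: the
    psychotropics composite (OR over the drug classes, opioids included) and
    suspected infection (admission-reason flag or CRP > 5 mg/L).
    """
    reg: list[VariableSpec] = [
        VariableSpec(OUTCOME_NAME, BINARY, role="outcome"),
        VariableSpec("age", CONTINUOUS, role="candidate", unit="years",
                     dichotomization=Dichotomization(75, "ge")),
        VariableSpec("dementia", BINARY, role="candidate"),
        VariableSpec("hearing_impairment", BINARY, role="candidate"),
    ]
    reg += [VariableSpec(c, BINARY, role="auxiliary") for c in PSYCHOTROPIC_CLASSES]
    reg += [
        VariableSpec("infection_reason", BINARY, role="auxiliary"),
        VariableSpec("crp", CONTINUOUS, role="auxiliary", unit="mg/L"),
        VariableSpec("systolic_bp", CONTINUOUS, role="candidate", unit="mmHg",
                     dichotomization=Dichotomization(120, "lt")),
        VariableSpec("sodium", CONTINUOUS, role="candidate", unit="mEq/L",
                     dichotomization=Dichotomization(135, "lt")),
        VariableSpec("haemoglobin", CONTINUOUS, role="candidate", unit="g/dL",
                     dichotomization=Dichotomization(10, "lt")),
        VariableSpec("psychotropics", BINARY, role="candidate",
                     derivation=Derivation("any_of", PSYCHOTROPIC_CLASSES)),
        VariableSpec("suspected_infection", BINARY, role="candidate",
                     derivation=Derivation("threshold_or_flag",
                                           ("infection_reason", "crp"), threshold=5.0)),
    ]
    return reg


#: Columns that feed derived flags and are never screened on their own.
KNOWN_AUXILIARY = set(PSYCHOTROPIC_CLASSES) | {
    "other_psychotropics", "infection_reason", "crp",
}


def infer_registry(df: pd.DataFrame, outcome: str = OUTCOME_NAME) -> list[VariableSpec]:
    """Best-effort registry for an arbitrary cohort CSV already in memory:
    columns whose non-missing values are all 0/1 become binary candidates,
    the rest continuous candidates.  Columns named like the known composite
    sources (drug subclasses, infection reason, CRP) become auxiliary."""
    if outcome not in df.columns:
        raise CohortValidationError(f"outcome column {outcome!r} not found")
    reg = [VariableSpec(outcome, BINARY, role="outcome")]
    for col in df.columns:
        if col in ("id", outcome):
            continue
        numeric = pd.to_numeric(df[col], errors="coerce")
        kind = BINARY if numeric.dropna().isin([0, 1]).all() else CONTINUOUS
        role = "auxiliary" if col in KNOWN_AUXILIARY else "candidate"
        reg.append(VariableSpec(col, kind, role=role))
    return reg
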
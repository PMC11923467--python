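"""Typed data model and delimited-text IO for two-arm trial datasets.

A trial dataset is a rectangular table of patient records with a separate
schema descriptor assigning each column a *kind* (continuous, binary,
categorical, event-time) and a *role* (treatment, outcome, event-indicator,
stratum, covariate, recruitment-index). Roles are semantic — which column is
the randomized arm, which columns were stratification factors — and cannot be
inferred from the data, so the descriptor is an explicit structured text
(YAML) file rather than something guessed at read time.

Conventions
-----------
* Records are CSV (UTF-8, header row). Categorical/binary values are stored
  as strings drawn from the declared level list; continuous and event-time
  values as floats; the recruitment index as a unique positive integer that
  totally orders the patients by accrual.
* The treatment variable is binary; its *second* declared level is the
  treated arm, the first the control arm. This fixes the sign convention of
  every downstream effect estimate.
* Missing values are rejected at read time.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

KINDS = ("continuous", "binary", "categorical", "event-time")
ROLES = (
    "treatment",
    "outcome",
    "event-indicator",
    "stratum",
    "covariate",
    "recruitment-index",
)


class SchemaError(ValueError):
    """A schema descriptor violates the data-model invariants."""


class TrialDataError(ValueError):
    """A record file does not conform to its schema."""


@dataclass(frozen=True)
class VariableSpec:
    """One column of a trial dataset.

    Parameters
    ----------
    name : column header.
    kind : one of ``continuous``, ``binary``, ``categorical``, ``event-time``.
    role : one of ``treatment``, ``outcome``, ``event-indicator``,
        ``stratum``, ``covariate``, ``recruitment-index``.
    levels : ordered label list, required for binary/categorical kinds.
    event_indicator : for event-time variables, the name of the paired
        binary event/censoring indicator column.
    """

    name: str
    kind: str
    role: str
    levels: tuple[str, ...] | None = None
    event_indicator: str | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for variable {self.name!r}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.kind in ("binary", "categorical"):
            if self.levels is None or len(self.levels) < 2:
                raise SchemaError(
                    f"variable {self.name!r}: {self.kind} kind requires >= 2 levels"
                )
            if self.kind == "binary" and len(self.levels) != 2:
                raise SchemaError(f"variable {self.name!r}: binary kind requires exactly 2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise SchemaError(f"variable {self.name!r}: duplicate levels")
        elif self.levels is not None:
            raise SchemaError(f"variable {self.name!r}: levels only allowed for discrete kinds")
        if self.kind == "event-time" and not self.event_indicator:
            raise SchemaError(
                f"variable {self.name!r}: event-time kind requires a paired event_indicator"
            )

    @property
    def is_discrete(self) -> bool:
        return self.kind in ("binary", "categorical")


@dataclass(frozen=True)
class TrialSchema:
    """Ordered variable list plus derived role lookups."""

    variables: tuple[VariableSpec, ...]

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names")
        idx = [v for v in self.variables if v.role == "recruitment-index"]
        if len(idx) != 1:
            raise SchemaError("exactly one recruitment-index variable is required")
        arms = [v for v in self.variables if v.role == "treatment"]
        if len(arms) > 1:
            raise SchemaError("at most one treatment variable")
        if arms and arms[0].kind != "binary":
            raise SchemaError("treatment variable must be binary")
        for v in self.variables:
            if v.role == "stratum" and not v.is_discrete:
                raise SchemaError(f"stratum {v.name!r} must be categorical or binary")
            if v.kind == "event-time":
                ind = self.get(v.event_indicator)
                if ind is None or ind.role != "event-indicator" or ind.kind != "binary":
                    raise SchemaError(
                        f"event-time {v.name!r} requires binary event-indicator "
                        f"{v.event_indicator!r} in the schema"
                    )

    # -- role lookups -------------------------------------------------------

    def get(self, name: str | None) -> VariableSpec | None:
        for v in self.variables:
            if v.name == name:
                return v
        return None

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def index_name(self) -> str:
        return next(v.name for v in self.variables if v.role == "recruitment-index")

    @property
    def arm_name(self) -> str | None:
        for v in self.variables:
            if v.role == "treatment":
                return v.name
        return None

    @property
    def strata_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "stratum"]

    @property
    def synth_names(self) -> list[str]:
        """Variables that generative models synthesize (everything but the index)."""
        return [v.name for v in self.variables if v.role != "recruitment-index"]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        out = []
        for v in self.variables:
            d: dict = {"name": v.name, "kind": v.kind, "role": v.role}
            if v.levels is not None:
                d["levels"] = list(v.levels)
            if v.event_indicator is not None:
                d["event_indicator"] = v.event_indicator
            out.append(d)
        return {"variables": out}

    @classmethod
    def from_dict(cls, d: dict) -> "TrialSchema":
        specs = []
        for item in d["variables"]:
            specs.append(
                VariableSpec(
                    name=str(item["name"]),
                    kind=item["kind"],
                    role=item["role"],
                    levels=tuple(str(x) for x in item["levels"]) if "levels" in item else None,
                    event_indicator=item.get("event_indicator"),
                )
            )
        return cls(tuple(specs))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class TrialDataset:
    """A validated, accrual-ordered trial dataset.

    ``data`` holds one row per patient with columns in schema order, sorted
    ascending by the recruitment index. Categorical/binary columns are string
    dtype, continuous and event-time columns float, the index integer.
    """

    schema: TrialSchema
    data: pd.DataFrame

    def __post_init__(self):
        self.data = self.data.loc[:, self.schema.names].reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.data)

    def sorted_by_accrual(self) -> "TrialDataset":
        return TrialDataset(
            self.schema,
            self.data.sort_values(self.schema.index_name, kind="mergesort"),
        )

    def arm01(self) -> np.ndarray:
        """Treatment as 0/1 (second declared level = treated = 1)."""
        name = self.schema.arm_name
        if name is None:
            raise TrialDataError("schema has no treatment variable")
        spec = self.schema.get(name)
        return (self.data[name].to_numpy() == spec.levels[1]).astype(int)


FAMILIES = (
    "mean-difference",
    "adjusted-linear",
    "logistic",
    "binary-robust",
    "cox",
    "survival-prob-difference",
    "descriptive-mean",
)

# outcome kind each analysis family expects
_FAMILY_KIND = {
    "mean-difference": "continuous",
    "adjusted-linear": "continuous",
    "descriptive-mean": "continuous",
    "logistic": "binary",
    "binary-robust": "binary",
    "cox": "event-time",
    "survival-prob-difference": "event-time",
}


@dataclass(frozen=True)
class AnalysisSpec:
    """How a trial's primary endpoint is analyzed.

    ``family`` names the published analysis style (difference in means,
    covariate-adjusted linear model, logistic regression, binomial GLM with
    sandwich SEs, Cox regression, difference in product-limit survival
    probabilities at a horizon, or a single-arm descriptive mean);
    ``outcome`` the endpoint column; ``covariates`` any adjustment columns;
    ``horizon`` the evaluation time for survival-probability differences.
    """

    family: str
    outcome: str
    covariates: tuple[str, ...] = ()
    horizon: float | None = None
    alpha: float = 0.05

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise SchemaError(f"unknown analysis family {self.family!r}")
        if not 0 < self.alpha < 1:
            raise SchemaError("alpha must be in (0, 1)")
        if self.family == "survival-prob-difference" and self.horizon is None:
            raise SchemaError("survival-prob-difference requires a horizon")

    def check_compatible(self, schema: TrialSchema) -> None:
        spec = schema.get(self.outcome)
        if spec is None:
            raise SchemaError(f"outcome {self.outcome!r} not in schema")
        want = _FAMILY_KIND[self.family]
        if spec.kind != want:
            raise SchemaError(
                f"family {self.family!r} expects a {want} outcome, "
                f"{self.outcome!r} is {spec.kind}"
            )


def _coerce(df: pd.DataFrame, schema: TrialSchema, path="<memory>") -> pd.DataFrame:
    out = {}
    for v in schema.variables:
        if v.name not in df.columns:
            raise TrialDataError(f"{path}: missing column {v.name!r}")
        col = df[v.name]
        if v.is_discrete:
            s = col.astype(str)
            bad = ~s.isin(v.levels)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise TrialDataError(
                    f"{path}: variable {v.name!r} row {row}: value {s.iloc[row]!r} "
                    f"not in declared levels {list(v.levels)}"
                )
            out[v.name] = s
        elif v.role == "recruitment-index":
            try:
                out[v.name] = pd.to_numeric(col, errors="raise").astype(int)
            except (ValueError, TypeError) as e:
                raise TrialDataError(f"{path}: non-integer recruitment index in {v.name!r}") from e
        else:
            try:
                out[v.name] = pd.to_numeric(col, errors="raise").astype(float)
            except (ValueError, TypeError) as e:
                raise TrialDataError(f"{path}: non-numeric value in continuous {v.name!r}") from e
    return pd.DataFrame(out)


def validate(ds: TrialDataset) -> list[str]:
    """Check every dataset invariant; return human-readable violations.

    Reports rather than throws, and is side-effect free: checks level
    membership, missing values, recruitment-index uniqueness, and
    non-negative event times.
    """
    out: list[str] = []
    df = ds.data
    for v in ds.schema.variables:
        if v.name not in df.columns:
            out.append(f"missing column {v.name!r}")
            continue
        col = df[v.name]
        if col.isna().any():
            out.append(f"variable {v.name!r}: missing values are not allowed")
        if v.is_discrete:
            bad = ~col.astype(str).isin(v.levels)
            if bad.any():
                out.append(
                    f"variable {v.name!r}: {int(bad.sum())} value(s) outside declared levels"
                )
        if v.kind == "event-time":
            vals = pd.to_numeric(col, errors="coerce")
            if (vals < 0).any():
                out.append(f"variable {v.name!r}: negative event time")
    idx_name = ds.schema.index_name
    if idx_name in df.columns and df[idx_name].duplicated().any():
        out.append(f"recruitment index {idx_name!r}: duplicate values")
    return out


def read_trial(path: str | Path, schema: TrialSchema | str | Path) -> TrialDataset:
    """Read a CSV record file against a schema and return a validated dataset.

    The result is sorted ascending by recruitment index regardless of row
    order on disk. Raises :class:`TrialDataError` on a missing column, a
    value outside its declared levels, a non-numeric continuous value, a
    missing value, or a duplicated recruitment index.
    """
    if not isinstance(schema, TrialSchema):
        schema = TrialSchema.from_yaml(schema)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.isin([""]).any().any() if len(raw) else False:
        col = raw.columns[(raw == "").any().to_numpy()][0]
        raise TrialDataError(f"{path}: empty (missing) value in column {col!r}")
    df = _coerce(raw, schema, path=str(path))
    ds = TrialDataset(schema, df).sorted_by_accrual()
    problems = validate(ds)
    if problems:
        raise TrialDataError(f"{path}: " + "; ".join(problems))
    return ds


def write_trial(ds: TrialDataset, path: str | Path) -> None:
    """Write records as CSV. ``read_trial(write_trial(ds))`` is lossless:
    floats are written at full precision and levels verbatim."""
    ds.data.to_csv(path, index=False)


def subset(ds: TrialDataset, mask) -> TrialDataset:
    return TrialDataset(ds.schema, ds.data.loc[mask])


__all__ = [
    "VariableSpec",
    "TrialSchema",
    "TrialDataset",
    "AnalysisSpec",
    "FAMILIES",
    "SchemaError",
    "TrialDataError",
    "read_trial",
    "write_trial",
    "validate",
    "subset",
]
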
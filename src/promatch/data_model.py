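"""Domain types and tabular I/O for arthroplasty-pathway cohorts.

The canonical cohort table has one row per patient and carries the
demographic/clinical covariates, the pathway assignment flag
(``fast_track``) and the SF-12 physical/mental summary scores at the
pre-operative visit and at 3 months after surgery.  CSV is the exchange
format; empty cells (plus ``NA``/``NaN``) denote missing values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, PreconditionError, SchemaError

# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

#: canonical column order of a cohort CSV
SCHEMA_FIELDS: tuple[str, ...] = (
    "patient_id",
    "age",
    "sex",
    "bmi",
    "out_of_region",
    "asa_class",
    "site",
    "pathology",
    "intervention",
    "septic",
    "length_of_surgery",
    "length_of_stay",
    "fast_track",
    "sf12_physical_pre",
    "sf12_mental_pre",
    "sf12_physical_3m",
    "sf12_mental_3m",
)

CONTINUOUS_FIELDS: tuple[str, ...] = (
    "age",
    "bmi",
    "length_of_surgery",
    "length_of_stay",
    "sf12_physical_pre",
    "sf12_mental_pre",
    "sf12_physical_3m",
    "sf12_mental_3m",
)

#: declared categories, in schema order (first = default reference level)
CATEGORICAL_LEVELS: Mapping[str, tuple] = {
    "sex": ("male", "female"),
    "asa_class": (1, 2, 3),
    "site": ("knee", "hip"),
    "pathology": ("primary", "secondary"),
    "intervention": ("first", "revision"),
}

BOOLEAN_FIELDS: tuple[str, ...] = ("out_of_region", "septic", "fast_track")

#: plausibility ranges; out-of-range cells are treated as missing on read
FIELD_RANGES: Mapping[str, tuple[float, float]] = {
    "age": (0.0, 120.0),
    "bmi": (10.0, 80.0),
    "length_of_surgery": (0.0, 600.0),
    "length_of_stay": (0.0, 365.0),
    "sf12_physical_pre": (0.0, 80.0),
    "sf12_mental_pre": (0.0, 80.0),
    "sf12_physical_3m": (0.0, 80.0),
    "sf12_mental_3m": (0.0, 80.0),
}

#: minimal adjustment set for pathway assignment (all arrows into both
#: treatment and outcome) plus the comparability extras bmi/sex/site
DEFAULT_PROPENSITY_COVARIATES: tuple[str, ...] = (
    "length_of_surgery",
    "sf12_physical_pre",
    "sf12_mental_pre",
    "age",
    "out_of_region",
    "asa_class",
    "intervention",
    "pathology",
    "bmi",
    "sex",
    "site",
)

_NA_STRINGS = {"", "na", "nan"}
_TRUE_STRINGS = {"true", "1", "yes", "y", "t"}
_FALSE_STRINGS = {"false", "0", "no", "n", "f"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientRecord:
    """One patient's covariates, pathway flag and SF-12 scores.

    Optional fields are ``None`` when missing.  Construction validates the
    schema invariants (age positive, ASA in {1,2,3}, SF-12 scores in
    [0, 80], BMI in (10, 80)).
    """

    patient_id: str
    age: float
    sex: str
    out_of_region: bool
    asa_class: int
    site: str
    pathology: str
    intervention: str
    septic: bool
    fast_track: bool
    bmi: float | None = None
    length_of_surgery: float | None = None
    length_of_stay: float | None = None
    sf12_physical_pre: float | None = None
    sf12_mental_pre: float | None = None
    sf12_physical_3m: float | None = None
    sf12_mental_3m: float | None = None

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.asa_class not in (1, 2, 3):
            raise ValueError(f"asa_class must be 1, 2 or 3, got {self.asa_class}")
        for name in ("sf12_physical_pre", "sf12_mental_pre",
                     "sf12_physical_3m", "sf12_mental_3m"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 80.0):
                raise ValueError(f"{name}={v} outside [0, 80]")
        if self.bmi is not None and not (10.0 < self.bmi < 80.0):
            raise ValueError(f"bmi={self.bmi} outside (10, 80)")
        for name, levels in CATEGORICAL_LEVELS.items():
            if name == "asa_class":
                continue
            if getattr(self, name) not in levels:
                raise ValueError(f"{name}={getattr(self, name)!r} not in {levels}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class FilterStep:
    """One entry of a cohort's filter audit trail."""

    name: str
    n_before: int
    n_after: int


@dataclass
class Cohort:
    """An ordered patient table plus the provenance of applied filters."""

    df: pd.DataFrame
    filter_log: list[FilterStep] = field(default_factory=list)
    missing_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.df["patient_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()[:5]
            raise InputError(f"duplicate patient_ids: {dupes}")
        for i, step in enumerate(self.filter_log):
            if step.n_after > step.n_before:
                raise InputError(f"filter_log step {step.name} increases n")
            if i and step.n_before > self.filter_log[i - 1].n_after:
                raise InputError("filter_log n values must be non-increasing")

    @property
    def n(self) -> int:
        return len(self.df)

    def with_filter(self, name: str, mask: pd.Series) -> "Cohort":
        """Return a new cohort keeping rows where ``mask`` is True, logging the step."""
        kept = self.df.loc[mask].reset_index(drop=True)
        log = [*self.filter_log, FilterStep(name, len(self.df), len(kept))]
        return Cohort(kept, log, dict(self.missing_counts))

    def to_records(self) -> list[PatientRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            kwargs = {}
            for k, v in d.items():
                if pd.isna(v):
                    kwargs[k] = None
                elif k == "asa_class":
                    kwargs[k] = int(v)
                elif k in BOOLEAN_FIELDS:
                    kwargs[k] = bool(v)
                else:
                    kwargs[k] = v
            out.append(PatientRecord(**kwargs))
        return out


@dataclass
class CovariateSpec:
    """Which covariates enter the propensity model and how they are coded.

    ``categorical_encoding`` maps a categorical field to its reference
    level; fields not listed default to the first category in schema
    order.  ``column_map`` renames CSV headers to canonical field names
    on read (e.g. ``{"ASA Class": "asa_class"}``).
    """

    propensity_covariates: Sequence[str] = DEFAULT_PROPENSITY_COVARIATES
    categorical_encoding: Mapping[str, object] = field(default_factory=dict)
    column_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.propensity_covariates:
            if name not in SCHEMA_FIELDS:
                raise SchemaError(f"unknown covariate {name!r}")
        for name, ref in self.categorical_encoding.items():
            levels = CATEGORICAL_LEVELS.get(name)
            if levels is None:
                raise SchemaError(f"{name!r} is not a categorical field")
            if ref not in levels:
                raise SchemaError(f"{ref!r} is not a category of {name!r}")

    def reference_level(self, name: str):
        if name in self.categorical_encoding:
            return self.categorical_encoding[name]
        return CATEGORICAL_LEVELS[name][0]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _parse_float(s: pd.Series, is_na: pd.Series) -> pd.Series:
    """Correctly-rounded decimal parsing (unparseable cells become NaN)."""
    def conv(v):
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan
    out = np.full(len(s), np.nan)
    mask = (~is_na).to_numpy()
    out[mask] = [conv(v) for v in s[~is_na]]
    return pd.Series(out, index=s.index)


def _parse_bool(raw: pd.Series) -> pd.Series:
    s = raw.astype("string").str.strip().str.lower()
    out = pd.Series(pd.NA, index=raw.index, dtype="boolean")
    out[s.isin(_TRUE_STRINGS)] = True
    out[s.isin(_FALSE_STRINGS)] = False
    return out


def read_cohort(path: str | Path, spec: CovariateSpec | None = None) -> Cohort:
    """Read a cohort CSV, coercing unparseable or out-of-range cells to missing.

    Returns a :class:`Cohort` whose ``missing_counts`` reports, per
    column, how many cells ended up missing (blank, ``NA``, unparseable
    or outside the plausibility range).

    Raises
    ------
    SchemaError
        if a required column is absent (after applying ``spec.column_map``).
    InputError
        if the file has no data rows.
    """
    spec = spec or CovariateSpec()
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty file") from None
    raw = raw.rename(columns=dict(spec.column_map))
    if len(raw) == 0:
        raise InputError(f"{path}: no data rows")
    for col in SCHEMA_FIELDS:
        if col not in raw.columns:
            raise SchemaError(f"missing required column {col!r}")

    out = pd.DataFrame(index=raw.index)
    missing: dict[str, int] = {}
    for col in SCHEMA_FIELDS:
        s = raw[col].astype("string").str.strip()
        is_na = s.str.lower().isin(_NA_STRINGS) | s.isna()
        if col == "patient_id":
            out[col] = s.astype(object)
            continue
        if col in BOOLEAN_FIELDS:
            vals = _parse_bool(s.where(~is_na))
        elif col == "asa_class":
            num = _parse_float(s, is_na)
            num[~num.isin([1, 2, 3])] = np.nan
            vals = num
        elif col in CATEGORICAL_LEVELS:
            low = s.str.lower().where(~is_na)
            levels = CATEGORICAL_LEVELS[col]
            vals = low.where(low.isin(levels), pd.NA).astype(object)
        else:
            num = _parse_float(s, is_na)
            lo, hi = FIELD_RANGES[col]
            num[(num < lo) | (num > hi)] = np.nan
            vals = num
        out[col] = vals
        missing[col] = int(pd.isna(vals).sum())
    return Cohort(out, filter_log=[], missing_counts=missing)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort table as UTF-8 CSV; missing values become empty cells."""
    df = cohort.df.copy()
    # integers render without a trailing .0 (asa_class reads back identically)
    if "asa_class" in df.columns:
        df["asa_class"] = df["asa_class"].map(
            lambda v: "" if pd.isna(v) else str(int(v)))
    for col in BOOLEAN_FIELDS:
        if col in df.columns:
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(bool(v)))
    for col in CONTINUOUS_FIELDS:
        if col in df.columns:
            # shortest-repr decimal text round-trips bit-for-bit
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df.to_csv(path, index=False, na_rep="", lineterminator="\n")


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def encode_design(
    cohort: Cohort | pd.DataFrame,
    spec: CovariateSpec | None = None,
    standardize: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Build the (patients x terms) design matrix for the propensity model.

    Continuous covariates pass through unchanged (optionally standardized
    to zero mean / unit SD for numerical conditioning); categorical and
    boolean covariates become reference-coded indicator columns over their
    *observed* levels (reference = spec reference if observed, else first
    observed level in schema order).  An intercept column comes first and
    the column order is deterministic: schema order of covariates,
    category order within a covariate.

    Raises :class:`PreconditionError` if any spec covariate has missing
    values (listing the offending patients).
    """
    spec = spec or CovariateSpec()
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    bad = df[list(spec.propensity_covariates)].isna().any(axis=1)
    if bad.any():
        ids = df.loc[bad, "patient_id"].tolist()
        shown = ", ".join(map(str, ids[:10]))
        more = f" (+{len(ids) - 10} more)" if len(ids) > 10 else ""
        raise PreconditionError(
            f"missing covariate values for patients: {shown}{more}")

    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    labels: list[str] = ["intercept"]
    for name in spec.propensity_covariates:
        values = df[name]
        if name in CONTINUOUS_FIELDS:
            x = values.to_numpy(dtype=float)
            if standardize:
                sd = x.std(ddof=1)
                x = (x - x.mean()) / (sd if sd > 0 else 1.0)
            cols.append(x)
            labels.append(name)
        elif name in BOOLEAN_FIELDS:
            observed = sorted(set(values.astype(bool)))
            if len(observed) == 2:
                cols.append(values.astype(bool).to_numpy().astype(float))
                labels.append(f"{name}=True")
            # single observed value: no information, no column
        elif name in CATEGORICAL_LEVELS:
            declared = CATEGORICAL_LEVELS[name]
            observed = [lv for lv in declared if (values == lv).any()]
            ref = spec.reference_level(name)
            if ref not in observed:
                ref = observed[0]
            for lv in observed:
                if lv == ref:
                    continue
                cols.append((values == lv).to_numpy().astype(float))
                labels.append(f"{name}={lv}")
        else:  # pragma: no cover - spec validation precludes this
            raise SchemaError(f"cannot encode covariate {name!r}")
    return np.column_stack(cols), labels


def missing_report(cohort: Cohort, fields: Iterable[str] | None = None) -> dict[str, float]:
    """Per-column missing-value *rates* (counts / n)."""
    fields = list(fields) if fields is not None else list(SCHEMA_FIELDS[1:])
    n = max(cohort.n, 1)
    return {f: float(cohort.df[f].isna().sum()) / n for f in fields}
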
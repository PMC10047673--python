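"""Cohort construction: complete-case filtering and clinical exclusion criteria.

Fast-track routing at the source hospital was decided by a pre-operative
questionnaire; patients carrying any feature that by itself rules out the
fast-track pathway (age over 80 years, ASA class III, septic infection,
secondary pathology, revision intervention) are removed from *both* arms
so that the compared populations are drawn from the same eligibility
envelope.  The "complexity of the pathology or procedure" criterion is
operationalised as pathology=secondary OR intervention=revision, the only
complexity-bearing fields in the schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .data_model import Cohort, SCHEMA_FIELDS
from .errors import ConfigError, PreconditionError, SchemaError

#: fields an analysis row must have observed (everything the models touch)
DEFAULT_REQUIRED_FIELDS: tuple[str, ...] = tuple(
    f for f in SCHEMA_FIELDS if f != "patient_id")


@dataclass(frozen=True)
class ExclusionRules:
    """Which patients are ineligible for the matched comparison.

    ``max_age`` is an exclusive upper bound: a patient aged exactly
    ``max_age`` is retained ("older than 80 years" excludes 81, not 80).
    """

    max_age: float = 80.0
    excluded_asa: frozenset = frozenset({3})
    exclude_septic: bool = True
    exclude_secondary: bool = True
    exclude_revision: bool = True

    def __post_init__(self) -> None:
        if not self.max_age > 0:
            raise ConfigError("max_age must be positive")


def drop_incomplete(cohort: Cohort,
                    required_fields: Sequence[str] = DEFAULT_REQUIRED_FIELDS) -> Cohort:
    """Keep only records with no missing value in any required field."""
    for f in required_fields:
        if f not in cohort.df.columns:
            raise SchemaError(f"required field {f!r} not in schema")
    mask = cohort.df[list(required_fields)].notna().all(axis=1)
    return cohort.with_filter("drop_incomplete", mask)


def apply_exclusions(cohort: Cohort,
                     rules: ExclusionRules = ExclusionRules()) -> Cohort:
    """Remove every patient satisfying at least one exclusion criterion.

    A record survives iff age <= max_age AND asa not excluded AND not
    septic AND (pathology primary, intervention first, under the default
    flags).  Exclusion fields must be complete (run :func:`drop_incomplete`
    first); missing values raise :class:`PreconditionError`.
    """
    df = cohort.df
    needed = ["age", "asa_class", "septic", "pathology", "intervention"]
    incomplete = df[needed].isna().any(axis=1)
    if incomplete.any():
        ids = df.loc[incomplete, "patient_id"].tolist()[:10]
        raise PreconditionError(
            f"exclusion fields missing for patients: {ids}")

    keep = pd.Series(True, index=df.index)
    keep &= df["age"] <= rules.max_age
    keep &= ~df["asa_class"].isin(list(rules.excluded_asa))
    if rules.exclude_septic:
        keep &= ~df["septic"].astype(bool)
    if rules.exclude_secondary:
        keep &= df["pathology"] == "primary"
    if rules.exclude_revision:
        keep &= df["intervention"] == "first"
    return cohort.with_filter("apply_exclusions", keep)
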
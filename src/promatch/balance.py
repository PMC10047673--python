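"""Covariate balance diagnostics before and after matching.

Three diagnostics per covariate, computed on the pre-match groups and on
the matched groups:

* standardized mean difference (SMD) -- below 0.1 is treated as
  negligible imbalance;
* variance ratio (VR, continuous covariates only) -- reported in the
  symmetric form max(r, 1/r) and required below 2;
* quantile-quantile point sets at percentiles 1..99 (continuous only),
  summarized by the mean |q_t - q_c| deviation from the diagonal.

The matched propensity-score distributions are additionally compared
with a Mann-Whitney test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (BOOLEAN_FIELDS, CATEGORICAL_LEVELS, CONTINUOUS_FIELDS,
                         Cohort, CovariateSpec)
from .errors import PreconditionError, SchemaError
from .matching import MatchResult
from .outcomes import mann_whitney_rbc

QQ_PERCENTILES = np.arange(1, 100)

DEFAULT_THRESHOLDS: Mapping[str, float] = {"smd": 0.1, "vr": 2.0}


def smd(values_t: Sequence[float], values_c: Sequence[float]) -> float:
    """Standardized mean difference between two samples (non-negative).

    Continuous: |m_t - m_c| / sqrt((s_t^2 + s_c^2) / 2) with sample
    (n-1) variances.  Samples containing only 0/1 are treated as binary
    indicators and use the p(1-p) variance.  Zero pooled variance returns
    0 when the means agree and +inf otherwise.
    """
    xt = np.asarray(values_t, dtype=float)
    xc = np.asarray(values_c, dtype=float)
    binary = set(np.unique(np.concatenate([xt, xc]))) <= {0.0, 1.0}
    if binary:
        pt, pc = xt.mean(), xc.mean()
        var = (pt * (1 - pt) + pc * (1 - pc)) / 2.0
        diff = abs(pt - pc)
    else:
        if len(xt) < 2 or len(xc) < 2:
            raise PreconditionError("need >= 2 values per group for continuous SMD")
        var = (xt.var(ddof=1) + xc.var(ddof=1)) / 2.0
        diff = abs(xt.mean() - xc.mean())
    if var == 0.0:
        return 0.0 if diff == 0.0 else math.inf
    return float(diff / math.sqrt(var))


def variance_ratio(values_t: Sequence[float], values_c: Sequence[float]) -> float:
    """Symmetric variance ratio max(r, 1/r), r = s_t^2 / s_c^2.

    The symmetric form bounds imbalance in either direction (a one-sided
    ratio would pass gross under-dispersion).  Zero variance in either
    group returns NaN (undefined).
    """
    xt = np.asarray(values_t, dtype=float)
    xc = np.asarray(values_c, dtype=float)
    if len(xt) < 2 or len(xc) < 2:
        raise PreconditionError("need >= 2 values per group for a variance ratio")
    vt, vc = xt.var(ddof=1), xc.var(ddof=1)
    if vt == 0.0 or vc == 0.0:
        return math.nan
    r = vt / vc
    return float(max(r, 1.0 / r))


def qq_points(values_t: Sequence[float], values_c: Sequence[float]) -> np.ndarray:
    """(99, 2) array of paired group quantiles at percentiles 1..99."""
    qt = np.percentile(np.asarray(values_t, dtype=float), QQ_PERCENTILES)
    qc = np.percentile(np.asarray(values_c, dtype=float), QQ_PERCENTILES)
    return np.column_stack([qt, qc])


@dataclass
class CovariateBalance:
    """Pre/post diagnostics for one covariate."""

    name: str
    smd_pre: float
    smd_post: float
    vr_pre: float | None = None          # continuous only
    vr_post: float | None = None
    qq_pre: np.ndarray | None = None     # (99, 2), continuous only
    qq_post: np.ndarray | None = None

    @property
    def qq_mean_abs_pre(self) -> float | None:
        if self.qq_pre is None:
            return None
        return float(np.mean(np.abs(self.qq_pre[:, 0] - self.qq_pre[:, 1])))

    @property
    def qq_mean_abs_post(self) -> float | None:
        if self.qq_post is None:
            return None
        return float(np.mean(np.abs(self.qq_post[:, 0] - self.qq_post[:, 1])))


@dataclass
class BalanceReport:
    """All covariate diagnostics plus the matched-score distribution test."""

    covariates: dict[str, CovariateBalance]
    ps_post_test_p: float
    thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    passed: bool = False
    smd_denominator: str = "within-sample"  # convention flag

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cb in self.covariates.values():
            rows.append({
                "covariate": cb.name,
                "smd_pre": cb.smd_pre, "smd_post": cb.smd_post,
                "vr_pre": cb.vr_pre, "vr_post": cb.vr_post,
                "qq_mean_abs_pre": cb.qq_mean_abs_pre,
                "qq_mean_abs_post": cb.qq_mean_abs_post,
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        def clean(v):
            if v is None:
                return None
            if isinstance(v, float) and math.isnan(v):
                return None
            return float(v) if isinstance(v, (float, np.floating)) else v
        return {
            "covariates": {
                name: {k: clean(v) for k, v in {
                    "smd_pre": cb.smd_pre, "smd_post": cb.smd_post,
                    "vr_pre": cb.vr_pre, "vr_post": cb.vr_post,
                    "qq_mean_abs_pre": cb.qq_mean_abs_pre,
                    "qq_mean_abs_post": cb.qq_mean_abs_post,
                }.items()}
                for name, cb in self.covariates.items()},
            "ps_post_test_p": float(self.ps_post_test_p),
            "thresholds": dict(self.thresholds),
            "passed": bool(self.passed),
            "smd_denominator": self.smd_denominator,
        }


def _covariate_columns(df: pd.DataFrame, name: str) -> dict[str, np.ndarray]:
    """Numeric views of one covariate: itself, or one 0/1 column per level."""
    if name in CONTINUOUS_FIELDS:
        return {name: df[name].to_numpy(dtype=float)}
    if name in BOOLEAN_FIELDS:
        return {name: df[name].astype(bool).to_numpy().astype(float)}
    if name in CATEGORICAL_LEVELS:
        return {f"{name}={lv}": (df[name] == lv).to_numpy().astype(float)
                for lv in CATEGORICAL_LEVELS[name]}
    raise SchemaError(f"unknown covariate {name!r}")


def balance_report(
    cohort: Cohort,
    match_result: MatchResult,
    spec: CovariateSpec | None = None,
    thresholds: Mapping[str, float] | None = None,
) -> BalanceReport:
    """Pre- and post-match balance diagnostics for every spec covariate.

    ``match_result.pairs`` must hold patient_ids of ``cohort``.  A
    multi-level categorical covariate's SMD is the maximum over its level
    indicators; VR and QQ sets are computed for continuous covariates
    only.  ``passed`` requires every post-match SMD below the SMD
    threshold and every defined post-match VR below the VR threshold.
    """
    spec = spec or CovariateSpec()
    thresholds = dict(DEFAULT_THRESHOLDS) | dict(thresholds or {})
    df = cohort.df
    for name in spec.propensity_covariates:
        if name not in df.columns:
            raise SchemaError(f"covariate {name!r} absent from cohort")

    treated = df["fast_track"].astype(bool).to_numpy()
    by_id = pd.Index(df["patient_id"])
    t_idx = by_id.get_indexer([p[0] for p in match_result.pairs])
    c_idx = by_id.get_indexer([p[1] for p in match_result.pairs])
    if (t_idx < 0).any() or (c_idx < 0).any():
        raise SchemaError("match result refers to ids not in cohort")

    out: dict[str, CovariateBalance] = {}
    for name in spec.propensity_covariates:
        columns = _covariate_columns(df, name)
        smd_pre_levels, smd_post_levels = [], []
        for col in columns.values():
            smd_pre_levels.append(smd(col[treated], col[~treated]))
            smd_post_levels.append(smd(col[t_idx], col[c_idx]))
        cb = CovariateBalance(name, max(smd_pre_levels), max(smd_post_levels))
        if name in CONTINUOUS_FIELDS:
            col = columns[name]
            cb.vr_pre = variance_ratio(col[treated], col[~treated])
            cb.vr_post = variance_ratio(col[t_idx], col[c_idx])
            cb.qq_pre = qq_points(col[treated], col[~treated])
            cb.qq_post = qq_points(col[t_idx], col[c_idx])
        out[name] = cb

    ps_p = mann_whitney_rbc(match_result.treated_scores,
                            match_result.control_scores)[1]
    smd_ok = all(cb.smd_post < thresholds["smd"] for cb in out.values())
    vr_ok = all(cb.vr_post < thresholds["vr"] for cb in out.values()
                if cb.vr_post is not None and not math.isnan(cb.vr_post))
    return BalanceReport(out, ps_p, thresholds, passed=bool(smd_ok and vr_ok))
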
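"""Matched-cohort outcome analysis for SF-12 physical and mental scores.

The 3-month score distributions of the two pathways are compared with a
Mann-Whitney U test and its rank-biserial correlation (RBC) effect size.
Improvement is a binary event -- a 3-month minus baseline change strictly
greater than the minimum clinically important difference (MCID, here the
distribution-based half-SD of the baseline scores) -- compared across the
matched pairs with McNemar's chi-squared test, a Cohen *d* on the
improvement indicator, and the number needed to treat (NNT) derived from
*d* through the normal-CDF conversion NNT = 1 / (2*Phi(d/sqrt(2)) - 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, PreconditionError

__all__ = [
    "mann_whitney_rbc",
    "compute_mcid",
    "classify_improvement",
    "mcnemar",
    "cohen_d_from_proportions",
    "nnt_from_d",
    "OutcomeComparison",
    "compare_outcomes",
]

_EXACT_MAX_N = 8


def mann_whitney_rbc(values_t, values_c) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U test with rank-biserial effect size.

    Returns ``(U, p, rbc)`` where U counts (t, c) pairs with t > c plus
    half the ties, and rbc = 2U/(n_t*n_c) - 1 (positive means the treated
    sample is stochastically larger).  The p-value is exact for small
    untied samples (both n <= 8) and otherwise uses the normal
    approximation with tie and continuity corrections.  Fully tied data
    return (n_t*n_c/2, 1, 0).
    """
    xt = np.asarray(values_t, dtype=float)
    xc = np.asarray(values_c, dtype=float)
    n1, n2 = len(xt), len(xc)
    if n1 == 0 or n2 == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([xt, xc])
    if np.all(pooled == pooled[0]):
        return n1 * n2 / 2.0, 1.0, 0.0
    has_ties = len(np.unique(pooled)) < n1 + n2
    method = "exact" if (max(n1, n2) <= _EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(xt, xc, alternative="two-sided", method=method,
                             use_continuity=True)
    u = float(res.statistic)
    rbc = 2.0 * u / (n1 * n2) - 1.0
    return u, float(res.pvalue), float(rbc)


def compute_mcid(pre_scores, sd_fraction: float = 0.5) -> float:
    """Distribution-based MCID: ``sd_fraction`` x sample SD of baselines.

    Computed on the pooled pre-operative scores of the analysis cohort
    (post-eligibility, before matching).  Zero baseline variance yields
    an MCID of 0 with a warning.
    """
    x = np.asarray(pre_scores, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise PreconditionError("need >= 2 baseline scores for an MCID")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        warnings.warn("zero baseline variance: MCID is 0", stacklevel=2)
    return sd_fraction * sd


def classify_improvement(pre, post, mcid: float) -> pd.Series:
    """Per-patient improvement flag: (post - pre) strictly greater than MCID.

    A change exactly equal to the MCID is *not* an improvement.  Patients
    with either score missing get ``pd.NA`` (nullable boolean output) and
    should be excluded, with a logged count, by the caller.
    """
    pre_s = pd.Series(np.asarray(pre, dtype=float))
    post_s = pd.Series(np.asarray(post, dtype=float))
    ok = pre_s.notna() & post_s.notna()
    out = pd.Series(pd.NA, index=pre_s.index, dtype="boolean")
    out[ok] = (post_s[ok] - pre_s[ok]) > mcid
    return out


def mcnemar(improved_t, improved_c, correction: bool = True
            ) -> tuple[float, float, int, int]:
    """McNemar test over matched pairs' improvement flags.

    Returns ``(chi2, p, b, c)`` with b = pairs where only the treated
    member improved and c = pairs where only the control member improved;
    chi2 = (|b - c| - 1)^2 / (b + c) with continuity correction (the -1
    is dropped when ``correction`` is False); p is the chi2_1 upper tail.
    No discordant pairs (b + c = 0) gives p = 1.
    """
    ft = np.asarray(improved_t, dtype=bool)
    fc = np.asarray(improved_c, dtype=bool)
    if len(ft) != len(fc):
        raise PreconditionError("flag vectors must be pair-aligned")
    b = int(np.sum(ft & ~fc))
    c = int(np.sum(~ft & fc))
    if b + c == 0:
        return 0.0, 1.0, b, c
    adj = 1.0 if correction else 0.0
    chi2 = (abs(b - c) - adj) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, b, c


def cohen_d_from_proportions(p_t: float, p_c: float) -> float:
    """Standardized difference of a binary indicator with pooled variance.

    d = (p_t - p_c) / sqrt((p_t(1-p_t) + p_c(1-p_c)) / 2); signed, so a
    positive value favours the treated group.  Degenerate proportions
    with zero pooled variance return NaN.
    """
    for p in (p_t, p_c):
        if not 0.0 <= p <= 1.0:
            raise PreconditionError(f"proportion {p} outside [0, 1]")
    var = (p_t * (1 - p_t) + p_c * (1 - p_c)) / 2.0
    if var == 0.0:
        return math.nan
    return (p_t - p_c) / math.sqrt(var)


def nnt_from_d(d: float) -> float:
    """Number needed to treat from a Cohen *d* via the normal-CDF formula.

    NNT = 1 / (2*Phi(|d|/sqrt(2)) - 1); always >= 1, strictly decreasing
    in |d| and -> 1 as |d| -> inf.  The sign of ``d`` says which group
    the NNT favours (the caller labels the direction); d = 0 returns
    +inf.
    """
    if d == 0.0 or math.isnan(d):
        return math.inf
    phi = stats.norm.cdf(abs(d) / math.sqrt(2.0))
    return float(1.0 / (2.0 * phi - 1.0))


@dataclass
class OutcomeComparison:
    """Every statistic of one outcome's matched-group comparison."""

    outcome_name: str
    n_t: int
    n_c: int
    mean_t: float
    mean_c: float
    mw_u: float
    mw_p: float
    rbc: float
    mcid: float
    improved_t: int
    improved_c: int
    prop_t: float
    prop_c: float
    mcnemar_chi2: float
    mcnemar_p: float
    mcnemar_b: int
    mcnemar_c: int
    cohen_d: float
    nnt: float
    nnt_favors: str          # "treated" / "control" / "none"
    n_pairs_excluded: int = 0

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, float) and (math.isnan(v) or math.isinf(v)):
                return None if math.isnan(v) else "inf"
            return v
        return {k: clean(v) for k, v in self.__dict__.items()}

    def display_row(self) -> dict:
        """Human-readable rounding: means/d 2 d.p., NNT 1 d.p."""
        return {
            "outcome": self.outcome_name,
            "mean_t": round(self.mean_t, 2),
            "mean_c": round(self.mean_c, 2),
            "mw_p": round(self.mw_p, 3),
            "rbc": round(self.rbc, 2),
            "improved": f"{100 * self.prop_t:.1f}% vs {100 * self.prop_c:.1f}%",
            "mcnemar_p": round(self.mcnemar_p, 3),
            "cohen_d": round(self.cohen_d, 2),
            "nnt": round(self.nnt, 1) if math.isfinite(self.nnt) else "inf",
            "nnt_favors": self.nnt_favors,
        }


def compare_outcomes(
    matched_df: pd.DataFrame,
    pairs: list[tuple],
    outcomes: dict[str, tuple[str, str]] | None = None,
    mcid_values: dict[str, float] | None = None,
    mcnemar_correction: bool = True,
) -> dict[str, OutcomeComparison]:
    """Full outcome analysis on a matched cohort.

    ``outcomes`` maps an outcome name to its (pre, post) column pair;
    defaults to the SF-12 physical and mental scores.  ``mcid_values``
    supplies the MCID per outcome; when absent it is computed as the
    half-SD of the pooled baselines *of the matched cohort* (pass values
    computed on the analysis cohort to follow the pre-match convention).
    The rank test treats the matched groups as independent samples; only
    McNemar uses the pairing.
    """
    outcomes = outcomes or {
        "sf12_physical": ("sf12_physical_pre", "sf12_physical_3m"),
        "sf12_mental": ("sf12_mental_pre", "sf12_mental_3m"),
    }
    mcid_values = mcid_values or {}
    by_id = pd.Index(matched_df["patient_id"])
    t_idx = by_id.get_indexer([p[0] for p in pairs])
    c_idx = by_id.get_indexer([p[1] for p in pairs])
    if (t_idx < 0).any() or (c_idx < 0).any():
        raise PreconditionError("pairs refer to ids not present in matched_df")

    results: dict[str, OutcomeComparison] = {}
    for name, (pre_col, post_col) in outcomes.items():
        pre = matched_df[pre_col].to_numpy(dtype=float)
        post = matched_df[post_col].to_numpy(dtype=float)
        vt, vc = post[t_idx], post[c_idx]
        u, p, rbc = mann_whitney_rbc(vt, vc)

        mcid = mcid_values.get(name)
        if mcid is None:
            mcid = compute_mcid(pre)
        flags = classify_improvement(pre, post, mcid)
        ft, fc = flags.iloc[t_idx].reset_index(drop=True), \
            flags.iloc[c_idx].reset_index(drop=True)
        ok = ft.notna() & fc.notna()
        excluded = int((~ok).sum())
        ftb = ft[ok].astype(bool).to_numpy()
        fcb = fc[ok].astype(bool).to_numpy()
        chi2, mp, bb, cc = mcnemar(ftb, fcb, correction=mcnemar_correction)
        n_pairs = int(ok.sum())
        prop_t = float(ftb.mean()) if n_pairs else math.nan
        prop_c = float(fcb.mean()) if n_pairs else math.nan
        d = cohen_d_from_proportions(prop_t, prop_c)
        nnt = nnt_from_d(d)
        favors = "none" if (not math.isfinite(nnt) or d == 0) else (
            "treated" if d > 0 else "control")
        results[name] = OutcomeComparison(
            outcome_name=name, n_t=len(vt), n_c=len(vc),
            mean_t=float(vt.mean()), mean_c=float(vc.mean()),
            mw_u=u, mw_p=p, rbc=rbc, mcid=float(mcid),
            improved_t=int(ftb.sum()), improved_c=int(fcb.sum()),
            prop_t=prop_t, prop_c=prop_c,
            mcnemar_chi2=chi2, mcnemar_p=mp, mcnemar_b=bb, mcnemar_c=cc,
            cohen_d=float(d), nnt=float(nnt), nnt_favors=favors,
            n_pairs_excluded=excluded)
    return results
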
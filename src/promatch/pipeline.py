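"""End-to-end orchestration: read -> eligibility -> propensity -> checks ->
match -> balance -> outcomes, with a machine-readable report bundle.

Every artefact of the run (filter audit trail, fitted model, stratum
diagnostics, pairs, balance tables, outcome comparisons, summary) is
written to the output directory as CSV/JSON; re-running with the same
config and input produces byte-identical JSON (there is no uncontrolled
randomness in the replication path).  In strict mode a failed
specification or balance check aborts the run, mirroring an analysis
protocol in which outcome comparison is conditional on the checks.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import eligibility as elig
from .balance import BalanceReport, balance_report
from .data_model import Cohort, CovariateSpec, encode_design, read_cohort
from .errors import CheckFailureError, ConfigError
from .matching import MatchResult, optimal_match
from .outcomes import OutcomeComparison, compare_outcomes, compute_mcid
from .propensity import DecileDiagnostics, PropensityFit, decile_checks, fit_propensity

OUTCOME_COLUMNS: Mapping[str, tuple[str, str]] = {
    "sf12_physical": ("sf12_physical_pre", "sf12_physical_3m"),
    "sf12_mental": ("sf12_mental_pre", "sf12_mental_3m"),
}


@dataclass
class PipelineConfig:
    """Everything one replication run needs; defaults encode the study protocol."""

    input_path: str | Path = ""
    output_dir: str | Path | None = None
    column_map: dict[str, str] = field(default_factory=dict)
    propensity_covariates: tuple[str, ...] | None = None  # None -> schema default
    required_fields: tuple[str, ...] = elig.DEFAULT_REQUIRED_FIELDS
    exclusion_rules: elig.ExclusionRules = field(default_factory=elig.ExclusionRules)
    alpha: float = 0.05
    smd_threshold: float = 0.1
    vr_threshold: float = 2.0
    mcid_sd_fraction: float = 0.5
    mcnemar_correction: bool = True
    caliper: float | None = None
    match_scale: str = "score"
    strict_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if self.smd_threshold <= 0 or self.vr_threshold <= 0:
            raise ConfigError("balance thresholds must be positive")
        if self.mcid_sd_fraction < 0:
            raise ConfigError("mcid_sd_fraction must be non-negative")

    def covariate_spec(self) -> CovariateSpec:
        if self.propensity_covariates is None:
            return CovariateSpec(column_map=self.column_map)
        return CovariateSpec(propensity_covariates=tuple(self.propensity_covariates),
                             column_map=self.column_map)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping")
        rules_raw = raw.pop("exclusion_rules", None)
        kwargs = {}
        names = {f.name for f in dataclasses.fields(cls)}
        for k, v in raw.items():
            if k not in names:
                raise ConfigError(f"unknown config key {k!r}")
            kwargs[k] = v
        if "propensity_covariates" in kwargs and kwargs["propensity_covariates"]:
            kwargs["propensity_covariates"] = tuple(kwargs["propensity_covariates"])
        if rules_raw:
            rules_raw = dict(rules_raw)
            if "excluded_asa" in rules_raw:
                rules_raw["excluded_asa"] = frozenset(rules_raw["excluded_asa"])
            kwargs["exclusion_rules"] = elig.ExclusionRules(**rules_raw)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """The full report bundle of one run."""

    cohort_raw: Cohort
    cohort_analysis: Cohort
    fit: PropensityFit
    diagnostics: DecileDiagnostics
    match: MatchResult
    balance: BalanceReport
    outcomes: dict[str, OutcomeComparison]
    mcids: dict[str, float]
    aborted_at: str | None = None

    @property
    def filter_log(self):
        return self.cohort_analysis.filter_log

    def summary(self) -> dict:
        s: dict = {
            "flow": [{"filter": st.name, "n_before": st.n_before,
                      "n_after": st.n_after}
                     for st in self.cohort_analysis.filter_log],
            "n_analysis": self.cohort_analysis.n,
            "n_treated": int(self.cohort_analysis.df["fast_track"].astype(bool).sum()),
            "checks": {
                "decile_passed": bool(self.diagnostics.passed),
                "balance_passed": bool(self.balance.passed),
                "ps_post_test_p": float(self.balance.ps_post_test_p),
            },
            "n_pairs": self.match.n_pairs,
            "n_matched_patients": 2 * self.match.n_pairs,
            "total_match_distance": self.match.total_distance,
            "mcid": {k: float(v) for k, v in self.mcids.items()},
            "outcomes": {k: v.to_dict() for k, v in self.outcomes.items()},
        }
        if self.aborted_at:
            s["aborted_at"] = self.aborted_at
        return s


def analysis_cohort(cohort: Cohort, config: PipelineConfig) -> Cohort:
    """Eligibility stage: complete-case filter then clinical exclusions."""
    c = elig.drop_incomplete(cohort, config.required_fields)
    return elig.apply_exclusions(c, config.exclusion_rules)


def match_cohort(cohort: Cohort, fit: PropensityFit,
                 config: PipelineConfig) -> MatchResult:
    """Optimal 1:1 matching of the analysis cohort on fitted scores."""
    treated = cohort.df["fast_track"].astype(bool).to_numpy()
    ids = cohort.df["patient_id"].to_numpy()
    return optimal_match(
        fit.scores[treated], fit.scores[~treated],
        treated_ids=ids[treated], control_ids=ids[~treated],
        caliper=config.caliper, scale=config.match_scale)


def run_pipeline(config: PipelineConfig,
                 cohort: Cohort | None = None) -> PipelineResult:
    """Execute every stage; write the report bundle if ``output_dir`` is set.

    In strict mode, a failed decile specification check or balance check
    raises :class:`CheckFailureError` after the diagnostics are written,
    so the failure is inspectable.
    """
    spec = config.covariate_spec()
    if cohort is None:
        cohort = read_cohort(config.input_path, spec)
    analysis = analysis_cohort(cohort, config)

    X, labels = encode_design(analysis, spec)
    treatment = analysis.df["fast_track"].astype(bool).to_numpy()
    fit = fit_propensity(X, treatment, labels)
    diag = decile_checks(fit, X, treatment, alpha=config.alpha)

    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_json(out_dir / "decile_diagnostics.json", diag.to_dict())
        _write_json(out_dir / "filter_log.json",
                    [dataclasses.asdict(s) for s in analysis.filter_log])
        _write_json(out_dir / "propensity_fit.json", {
            "coefficients": dict(zip(fit.labels, map(float, fit.coefficients))),
            "converged": fit.converged, "n_iterations": fit.n_iterations,
            "log_likelihood": fit.log_likelihood,
        })
        scores_df = pd.DataFrame({"patient_id": analysis.df["patient_id"],
                                  "fast_track": treatment,
                                  "propensity_score": fit.scores})
        scores_df.to_csv(out_dir / "propensity_scores.csv", index=False)
    if not diag.passed and config.strict_mode:
        raise CheckFailureError("decile specification checks failed")

    match = match_cohort(analysis, fit, config)
    bal = balance_report(analysis, match, spec,
                         {"smd": config.smd_threshold, "vr": config.vr_threshold})
    if out_dir:
        pd.DataFrame({
            "treated_id": [p[0] for p in match.pairs],
            "control_id": [p[1] for p in match.pairs],
            "e_t": match.treated_scores, "e_c": match.control_scores,
            "distance": match.per_pair_distance,
        }).to_csv(out_dir / "pairs.csv", index=False)
        bal.to_frame().to_csv(out_dir / "balance.csv", index=False)
        _write_json(out_dir / "balance.json", bal.to_dict())
        _write_matched_cohort(out_dir / "matched_cohort.csv", analysis, match)
    if not bal.passed and config.strict_mode:
        raise CheckFailureError("post-match balance checks failed")

    mcids = {name: compute_mcid(analysis.df[pre], config.mcid_sd_fraction)
             for name, (pre, _) in OUTCOME_COLUMNS.items()}
    matched_ids = {p for pair in match.pairs for p in pair}
    matched_df = analysis.df[analysis.df["patient_id"].isin(matched_ids)]
    comparisons = compare_outcomes(
        matched_df, match.pairs, dict(OUTCOME_COLUMNS), mcids,
        mcnemar_correction=config.mcnemar_correction)

    result = PipelineResult(cohort, analysis, fit, diag, match, bal,
                            comparisons, mcids)
    if out_dir:
        pd.DataFrame([c.to_dict() for c in comparisons.values()]).to_csv(
            out_dir / "outcomes.csv", index=False)
        _write_json(out_dir / "outcomes.json",
                    {k: v.to_dict() for k, v in comparisons.items()})
        _write_json(out_dir / "summary.json", result.summary())
    return result


def report_summary(result: PipelineResult) -> str:
    """Human-readable run report: patient flow, checks, outcome table."""
    lines = ["Patient flow"]
    for st in result.filter_log:
        lines.append(f"  {st.name}: {st.n_before} -> {st.n_after}")
    lines.append(f"  analysis cohort: {result.cohort_analysis.n} "
                 f"({result.summary()['n_treated']} fast-track)")
    lines.append("Checks")
    lines.append(f"  decile specification checks: "
                 f"{'pass' if result.diagnostics.passed else 'FAIL'}")
    lines.append(f"  post-match balance (SMD<{result.balance.thresholds['smd']}, "
                 f"VR<{result.balance.thresholds['vr']}): "
                 f"{'pass' if result.balance.passed else 'FAIL'}")
    lines.append(f"Matched pairs: {result.match.n_pairs} "
                 f"({2 * result.match.n_pairs} patients), "
                 f"total score distance {result.match.total_distance:.4f}")
    lines.append("Outcomes")
    for comp in result.outcomes.values():
        row = comp.display_row()
        lines.append(
            f"  {row['outcome']}: means {row['mean_t']} vs {row['mean_c']} "
            f"(MW p={row['mw_p']}, RBC={row['rbc']}); improved {row['improved']} "
            f"(McNemar p={row['mcnemar_p']}, d={row['cohen_d']}, "
            f"NNT={row['nnt']} favouring {row['nnt_favors']})")
    if result.aborted_at:
        lines.append(f"RUN ABORTED AT: {result.aborted_at}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if (math.isnan(f) or math.isinf(f)) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def _write_matched_cohort(path: Path, analysis: Cohort, match: MatchResult) -> None:
    pair_of: dict = {}
    for k, (t, c) in enumerate(match.pairs):
        pair_of[t] = k
        pair_of[c] = k
    df = analysis.df[analysis.df["patient_id"].isin(pair_of)].copy()
    df["pair_id"] = df["patient_id"].map(pair_of)
    df.to_csv(path, index=False, na_rep="", lineterminator="\n")


def naive_and_matched_estimates(cohort: Cohort, config: PipelineConfig,
                                outcome: str = "sf12_physical"
                                ) -> tuple[float, float, int, float]:
    """Lean estimation path for simulation studies.

    Runs eligibility, the propensity fit and optimal matching (skipping
    the advisory decile/balance diagnostics) and returns
    ``(naive_diff, matched_diff, n_pairs, matched_mw_p)`` for the given
    outcome: the unadjusted treated-control difference of 3-month means
    on the analysis cohort, and the matched-pair difference of means.
    """
    analysis = analysis_cohort(cohort, config)
    spec = config.covariate_spec()
    X, labels = encode_design(analysis, spec)
    treatment = analysis.df["fast_track"].astype(bool).to_numpy()
    fit = fit_propensity(X, treatment, labels)
    match = match_cohort(analysis, fit, config)

    _, post_col = OUTCOME_COLUMNS[outcome]
    post = analysis.df[post_col].to_numpy(dtype=float)
    naive = float(post[treatment].mean() - post[~treatment].mean())

    by_id = pd.Index(analysis.df["patient_id"])
    t_idx = by_id.get_indexer([p[0] for p in match.pairs])
    c_idx = by_id.get_indexer([p[1] for p in match.pairs])
    vt, vc = post[t_idx], post[c_idx]
    matched = float(vt.mean() - vc.mean())
    from .outcomes import mann_whitney_rbc
    p = mann_whitney_rbc(vt, vc)[1]
    return naive, matched, match.n_pairs, p
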
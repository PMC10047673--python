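# Methods

## Design

The package estimates the effect of a fast-track arthroplasty pathway on
3-month SF-12 physical and mental scores from a retrospective two-arm
cohort.  Because pathway assignment is a triage decision driven by the
same pre-operative characteristics that predict recovery, the analysis
is built around propensity score matching: model `e(x) = P(T=1|x)`,
check the model's specification, pair each patient of the smaller arm
with a distinct patient of the larger arm so that total score distance
is minimal, verify covariate balance, and only then compare outcomes.
The estimand is the pathway effect on the matched population; with the
homogeneous effects of the synthetic generator it coincides with the
average treatment effect.

## Eligibility

Analysis rows are complete cases on every modelled field.  Patients
carrying any feature that by itself precludes fast-track routing are
then removed from both arms: age strictly greater than 80 years (a
patient aged exactly 80 is retained), ASA class III, post-surgical
septic infection, secondary pathology or revision intervention.  The
"complex pathology/procedure" criterion has no dedicated field in the
schema; it is operationalised as `pathology = secondary OR intervention
= revision`, the only complexity-bearing fields available.  Both filters
commute and are idempotent; the audit trail records counts at each step.

## Propensity model and specification checks

The assignment model is logistic regression fitted by IRLS
(convergence: max |Δβ| < 1e-8 or 100 iterations; perfect separation
reported when ‖β‖∞ exceeds 1e4).  Covariates enter in natural units —
propensity scores are invariant to affine covariate rescaling, so
matching is unaffected; a standardization flag exists purely for
numerical conditioning.  Categoricals are reference-coded over their
*observed* levels (reference = first observed category in schema order):
after the eligibility filter several fields are constant and full-level
coding would make the design singular.

Specification checks: patients are ranked by fitted score and split into
10 strata of near-equal size (ties broken by input order, so the
assignment is deterministic).  Within each stratum, treated and control
patients are compared — on the score itself and on every design column —
with two-sided Mann–Whitney U tests; p-values are Bonferroni-adjusted
within each family of 10 and capped at 1.  Bonferroni is used because it
reproduces the familiar pattern of many adjusted values exactly 1 and
the ×10 scaling of a borderline raw p.  A stratum in which one group is
empty cannot be tested; its p is set to 1 and the stratum is flagged.
The checks are advisory: the pipeline warns on failure and halts only in
strict mode.  With ~110 adjusted tests per run they retain a
non-trivial family-wise false-alarm rate — individual synthetic
replicates do occasionally fail a check by chance even though the model
is exactly correct.

## Matching

Matching minimises Σ|e_t − e_c| over 1:1 pairs — a rectangular linear
assignment problem solved exactly with a shortest-augmenting-path
(Jonker–Volgenant family) solver.  Every member of the smaller arm is
matched; the optimum selects the members of the larger arm.  Distances
are computed on the probability scale by default (a logit-scale option
exists), and no caliper is applied by default.  Results are
deterministic given input order, with pairs reported in treated input
order.  A brute-force enumeration oracle (groups ≤ 8) verifies global
optimality in the tests, and equal-size 1-D instances are checked
against the rank-to-rank closed form.

## Balance diagnostics

Per covariate, pre- and post-match: SMD (continuous: pooled-SD form with
(n−1) variances; binary: p(1−p) variances; multi-level categorical:
maximum over level indicators), symmetric variance ratio max(r, 1/r)
(continuous only; the symmetric form also fails gross under-dispersion,
which a one-sided ratio would pass), and QQ point sets at percentiles
1–99 summarised by mean |q_t − q_c|.  Post-match SMDs standardise by the
matched groups' own SDs (the simpler convention; flagged in the report
metadata since some software standardises by pre-match SDs).  The
balance gate requires every post-match SMD < 0.1 and every defined
post-match VR < 2.

## Outcome analysis

Three-month scores are compared with the Mann–Whitney U test and the
rank-biserial correlation; the matched groups are deliberately treated
as independent samples for this test (only McNemar exploits the
pairing), which makes the rank test mildly conservative under the null —
visible as a sub-nominal type-I rate in the replicate experiment.
Improvement is `(post − pre) > MCID`, strict, with the distribution-based
MCID 0.5 × SD of the pooled baseline scores of the post-eligibility
analysis cohort (computed before matching).  Half-SD is the most common
distribution-based variant; SEM-based variants exist and would shift the
improvement percentages, so the choice is flagged in the report.
Discordant pair counts feed McNemar's χ² with continuity correction
(`(|b−c|−1)²/(b+c)`, p from χ²₁; b+c=0 gives p=1; a no-correction flag
exists).  At the knife edge b=c the corrected statistic is 1/(b+c)
rather than 0 — the conventional formula's behaviour, retained as such.
Cohen d on the improvement indicator uses the pooled binary variance;
this definition, chained through `NNT = 1/(2Φ(|d|/√2) − 1)`, exactly
reproduces the d → NNT pairs of the matched fast-track study from its
printed improvement percentages, which is the package's numeric
cross-validation of the formula interpretation.  The NNT is labeled with
the direction (which arm it favours); d=0 yields an infinite sentinel.

## Synthetic cohort generator

The generator emulates the marginal structure of a large elective
hip/knee replacement service: age truncated-normal (mean 68.72, SD
10.96, range 40–95, with a configurable 15% mass above 80), BMI
normal-truncated (27.39 ± 4.73), length of surgery 93.98 ± 34.48 min,
baseline SF-12 physical 32.10 ± 7.70 and mental 49.69 ± 12.54, 41%
female, 18% out-of-region, 55% knee, ASA III 7%, secondary pathology
16%, revision 9%, septic 2%, and MCAR missingness (BMI 1%, lengths 2%).
Treatment is Bernoulli(expit(β·x)) with mean-centered continuous terms;
outcomes are `post = pre + γ·x + τ·T + N(0, σ)` clipped to [0, 80], with
defaults τ_physical = 2.0, τ_mental = 0, σ = 6.0 — calibrated once so
that matched-analysis power at n ≈ 1000 is moderate, mimicking small
real-world pathway effects; they are a design choice, not estimates.
The β/γ sign pattern (younger, fitter, shorter-surgery, lower-ASA
patients both preferentially fast-tracked and recovering better) makes
several covariates genuine confounders; the assignment intercept (1.10)
and slope magnitudes were fixed by Monte-Carlo calibration so the
treated fraction is ≈ 0.66 and overlap is realistic — strong enough that
the naive contrast is biased by ≈ +1.5 points (≫ its Monte-Carlo error),
weak enough that optimal matching on a correctly specified score removes
the bias to within Monte-Carlo error at n = 1000.

Each field draws from its own RNG stream (global seed + CRC32 of the
field name), so adding a field never perturbs existing ones and equal
seeds give byte-identical CSVs.

What the generator does *not* emulate — and therefore what passing tests
do not establish about real data: informative missingness, unmeasured
confounding, effect heterogeneity, non-linear or interaction terms in
assignment or outcome models, clustered care episodes, or floor/ceiling
measurement artefacts beyond simple clipping.  A real cohort analysis
stands or falls with the no-unmeasured-confounding assumption, which no
synthetic check can validate.

## Numerical conventions

- Mann–Whitney: exact null distribution for untied samples with both
  n ≤ 8; otherwise normal approximation with tie and continuity
  corrections.  Fully tied data return (U = n_t·n_c/2, p = 1, rbc = 0).
- Decile edges follow the rank-based assignment (sizes differ by at most
  one when scores are distinct); reported edges are per-stratum maxima.
- Zero-variance sentinels: SMD → 0 on equal means else +inf; VR → NaN;
  degenerate proportions in Cohen d → NaN; d = 0 → infinite NNT.
- CSV floats are written as shortest-repr decimal text and parsed with
  correctly-rounded conversion, so write → read → write is
  byte-identical.
- JSON outputs are sorted and fully deterministic; re-running a pipeline
  on identical input reproduces the bundle byte for byte.

## Problem sizes

The replicate experiments run 100 replicates at n = 1000 (tests) and 50
(analysis script); oracle comparisons use 200 random matching instances
with groups ≤ 8, exhaustive rank enumeration for small Mann–Whitney
samples, a b/c grid for McNemar vs the exact binomial, and one n = 20000
draw for coefficient recovery within 3 asymptotic standard errors.
These sizes were chosen so each check's Monte-Carlo error is small
relative to the effect it measures.

## Known limitations

- 1:1 matching without replacement only; no 1:k, full, or caliper-first
  designs (a post-hoc caliper option exists).
- No confidence intervals for the NNT; no variance adjustment of the
  rank test for the matched design.
- Complete-case analysis only — principled under MCAR, untestable
  otherwise; no imputation.
- The eligibility operationalisation of "complex pathology/procedure"
  is an interpretation forced by the schema (see docs above); audit
  counts on external datasets may differ if complexity was recorded
  elsewhere.
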
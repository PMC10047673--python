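# promatch

Propensity-score-matched comparison of **fast-track** versus
**care-as-usual** hip/knee arthroplasty pathways on SF-12
patient-reported outcomes, built as a tested, reusable pipeline:
eligibility filtering → logistic propensity estimation with
specification checks → optimal 1:1 matching → covariate balance
diagnostics → outcome effect sizes, MCID improvement rates and the
number needed to treat.

## Who this is for

Fast-track (enhanced-recovery) pathways mobilise arthroplasty patients
within hours of surgery and discharge them early.  Whether the *whole*
pathway — including rehabilitation — improves how patients themselves
rate their health is an observational question: pathway assignment is
decided by a pre-operative triage, so treated and control patients
differ systematically.  This package implements the standard
bias-correction design for that question (propensity score matching on a
retrospective cohort) for anyone analysing SF-12-style PROM data from a
two-pathway service, and ships a synthetic-cohort generator with known
confounding and a known treatment effect so every stage of the pipeline
is verifiable without access to patient data.

## The statistics

- **Propensity score** `e(x) = P(T=1 | x)`, fitted by maximum-likelihood
  logistic regression (IRLS) on the minimal adjustment set (length of
  surgery, baseline SF-12 physical/mental, age, out-of-region, ASA
  class, first/revision, primary/secondary) plus BMI, sex and site for
  comparability.  Model specification is checked per decile of the
  pooled score distribution with Mann–Whitney U tests
  (Bonferroni-adjusted within each 10-test family).
- **Optimal 1:1 matching** minimising the total `|e_t − e_c|` over
  pairs — a rectangular linear assignment problem solved exactly, not
  greedily.
- **Balance**: standardized mean differences (`< 0.1`), symmetric
  variance ratios (`< 2`) and quantile–quantile point sets, pre and post
  match.
- **Outcomes** at 3 months: Mann–Whitney U with rank-biserial
  correlation `rbc = 2U/(n_t n_c) − 1`; improvement =
  `(post − pre) > MCID` with the distribution-based MCID
  `0.5 × SD(baseline)`; McNemar χ² over matched pairs; Cohen
  `d = (p_t − p_c)/√((p_t(1−p_t)+p_c(1−p_c))/2)` on the improvement
  indicator; and `NNT = 1 / (2Φ(d/√2) − 1)`.

## Worked example

```bash
python analysis/01_simulate_cohort.py     # synthetic cohort + ground truth
python analysis/02_run_pipeline.py        # full matched analysis
```

The default synthetic cohort draws 1600 patients (66% fast-track,
true physical-score effect +2.0 points).  The pipeline prints:

```
Patient flow
  drop_incomplete: 1600 -> 1520
  apply_exclusions: 1520 -> 941
  analysis cohort: 941 (673 fast-track)
Checks
  decile specification checks: pass
  post-match balance (SMD<0.1, VR<2.0): pass
Matched pairs: 268 (536 patients), total score distance 0.5237
Outcomes
  sf12_physical: means 42.34 vs 40.27 (MW p=0.013, RBC=0.12); improved 86.6% vs 81.7% (McNemar p=0.16, d=0.13, NNT=13.3 favouring treated)
  sf12_mental: means 51.98 vs 51.84 (MW p=0.87, RBC=0.01); improved 32.1% vs 28.4% (McNemar p=0.395, d=0.08, NNT=21.8 favouring treated)

matched mean difference (physical): 2.07 score points (generative treatment effect: 2.0)
```

Reading it: 96 records fall to complete-case filtering, 579 to the
eligibility criteria (age > 80, ASA III, septic, secondary pathology,
revision).  All 268 controls are matched; after matching, every
covariate's SMD is below 0.1.  The naive treated-control contrast on
this cohort is ≈ +3.6 points (biased — fitter patients are routed
fast-track); the matched contrast, 2.07, recovers the true +2.0.  The
mental score, simulated with zero treatment effect, shows the expected
null (RBC 0.01, p 0.87).

The same stages are exposed as a CLI (`promatch simulate | filter | fit |
match | balance | analyze | run | report`); `promatch run --config
configs/replication.yaml` executes the whole protocol on a cohort CSV
with the canonical column schema.

## Layout

```
src/promatch/      library: data_model, synthetic, eligibility,
                   propensity, matching, balance, outcomes, pipeline, cli
analysis/          numbered narrative drivers writing to results/
configs/           replication.yaml (full protocol defaults)
scripts/           acceptance.py
tests/             pytest suite (unit, property and end-to-end checks)
docs/methods.md    models, conventions and design decisions
```
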
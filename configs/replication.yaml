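# Replication defaults for the fast-track vs care-as-usual matched analysis.
# Point input_path at the deposited cohort CSV (canonical column names, see
# README) and run:  promatch run --config configs/replication.yaml --out <dir>
input_path: data/cohort.csv
output_dir: results/replication

# eligibility: complete-case analysis plus the routing exclusion criteria
exclusion_rules:
  max_age: 80          # exclusive bound: exactly 80 is retained
  excluded_asa: [3]
  exclude_septic: true
  exclude_secondary: true
  exclude_revision: true

# propensity model: minimal adjustment set plus bmi/sex/site (schema default)
alpha: 0.05            # decile specification-check level (Bonferroni-adjusted)
smd_threshold: 0.1
vr_threshold: 2.0
mcid_sd_fraction: 0.5  # distribution-based MCID: half the baseline SD
mcnemar_correction: true
match_scale: score     # distances on e(x), not logit(e)
caliper: null
strict_mode: true      # outcome analysis conditional on passing checks
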
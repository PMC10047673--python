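#!/usr/bin/env python
"""Draw the default synthetic arthroplasty cohort and record its ground truth.

Writes the full cohort CSV (regenerable, so it lives under scratch/) plus
a small summary table under results/: marginal means, pathway mix and the
generative treatment effects the downstream pipeline must recover.
"""

import json
from pathlib import Path

import yaml

from promatch.data_model import missing_report, write_cohort
from promatch.synthetic import SimulationConfig, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = 0  # the generator's default draw


def main() -> None:
    config = SimulationConfig(seed=SEED)
    cohort, truth = simulate_cohort(config)

    out = ROOT / "scratch" / "synthetic"
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(cohort, out / "cohort.csv")
    (out / "truth.yaml").write_text(yaml.safe_dump({
        "seed": SEED, "n": config.n,
        "tau_physical": truth.tau_physical, "tau_mental": truth.tau_mental,
        "beta_treat": dict(truth.beta_treat),
        "treated_fraction": truth.treated_fraction,
    }, sort_keys=True))

    df = cohort.df
    summary = {
        "n": cohort.n,
        "treated_fraction": round(truth.treated_fraction, 4),
        "age_mean": round(df["age"].mean(), 2),
        "bmi_mean": round(df["bmi"].mean(), 2),
        "sf12_physical_pre_mean": round(df["sf12_physical_pre"].mean(), 2),
        "sf12_physical_3m_mean": round(df["sf12_physical_3m"].mean(), 2),
        "missing_rates": {k: round(v, 4) for k, v in missing_report(
            cohort, ["bmi", "length_of_surgery", "length_of_stay"]).items()},
        "true_tau_physical": truth.tau_physical,
        "true_tau_mental": truth.tau_mental,
    }
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    (res / "01_cohort_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    print(f"cohort of {cohort.n} patients written to {out / 'cohort.csv'}")
    print(json.dumps(summary, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
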
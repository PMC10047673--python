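"""Synthetic arthroplasty cohorts with known confounding and treatment effect.

The generator emulates the statistical structure the matched analysis
assumes: covariates drawn from marginals calibrated to a real elective
hip/knee replacement service (mean age ~69, BMI ~27, ~66% on the
fast-track pathway), a *known* logistic treatment-assignment model so the
true propensity of every simulated patient is available, and 3-month
SF-12 scores built additively from the baseline score, covariate effects,
a homogeneous pathway effect tau and Gaussian noise.  Because several
covariates carry non-zero coefficients in both the assignment and the
outcome models, the naive treated-vs-control contrast is confounded by
construction and the matching pipeline has real bias to remove.

Each field is drawn from its own counter-based RNG stream (derived from
the global seed and the field name), so adding a field to the generator
does not perturb the values of existing fields.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .data_model import Cohort
from .errors import ConfigError

__all__ = [
    "CovariateMarginals",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_null_improvement",
    "DEFAULT_BETA_TREAT",
    "DEFAULT_GAMMA_PHYSICAL",
    "DEFAULT_GAMMA_MENTAL",
]


@dataclass(frozen=True)
class CovariateMarginals:
    """Marginal covariate distributions (units: years, kg/m2, minutes, days)."""

    age_mean: float = 68.72
    age_sd: float = 10.96
    age_min: float = 40.0
    age_max: float = 95.0
    bmi_mean: float = 27.39
    bmi_sd: float = 4.73
    bmi_min: float = 16.0
    bmi_max: float = 55.0
    surgery_mean: float = 93.98
    surgery_sd: float = 34.48
    surgery_min: float = 20.0
    surgery_max: float = 300.0
    stay_mean: float = 4.01
    stay_sd: float = 1.95
    stay_min: float = 1.0
    stay_max: float = 30.0
    physical_pre_mean: float = 32.10
    physical_pre_sd: float = 7.70
    mental_pre_mean: float = 49.69
    mental_pre_sd: float = 12.54
    p_female: float = 0.41
    p_out_of_region: float = 0.18
    p_knee: float = 0.55
    p_asa1_given_eligible: float = 0.118  # 0.11 / (0.11 + 0.82) of the non-ASA-III mass


#: true assignment model, log-odds units per natural covariate unit.
#: Continuous terms are mean-centered when the linear predictor is built,
#: so "intercept" is the log-odds of fast-track for an average patient in
#: the reference categories.  Sign pattern: younger, fitter (higher
#: baseline physical score), shorter-surgery, lower-ASA patients are more
#: likely to be routed fast-track -- the confounding the study corrects.
DEFAULT_BETA_TREAT: Mapping[str, float] = {
    "intercept": 1.10,
    "age": -0.025,
    "sf12_physical_pre": 0.025,
    "sf12_mental_pre": 0.01,
    "length_of_surgery": -0.005,
    "bmi": -0.01,
    "out_of_region=True": -0.15,
    "asa_class=2": -0.20,
    "asa_class=3": -0.60,
    "site=hip": -0.05,
    "pathology=secondary": -0.25,
    "intervention=revision": -0.40,
    "septic=True": -0.75,
    "sex=female": -0.05,
}

#: true covariate effects on the 3-month minus baseline physical-score change
DEFAULT_GAMMA_PHYSICAL: Mapping[str, float] = {
    "intercept": 10.0,
    "age": -0.08,
    "sf12_physical_pre": -0.15,
    "sf12_mental_pre": 0.02,
    "length_of_surgery": -0.015,
    "bmi": -0.08,
    "out_of_region=True": -0.50,
    "asa_class=2": -1.00,
    "asa_class=3": -2.50,
    "site=hip": 0.50,
    "pathology=secondary": -1.00,
    "intervention=revision": -1.50,
    "septic=True": -3.00,
    "sex=female": -0.30,
}

DEFAULT_GAMMA_MENTAL: Mapping[str, float] = {
    "intercept": 2.9,
    "age": -0.02,
    "sf12_physical_pre": 0.02,
    "sf12_mental_pre": -0.25,
    "length_of_surgery": 0.0,
    "bmi": 0.0,
    "out_of_region=True": -0.30,
    "asa_class=2": -0.50,
    "asa_class=3": -1.00,
    "site=hip": 0.0,
    "pathology=secondary": 0.0,
    "intervention=revision": 0.0,
    "septic=True": -2.00,
    "sex=female": 0.0,
}

DEFAULT_MISSING_RATES: Mapping[str, float] = {
    "bmi": 0.01,
    "length_of_surgery": 0.02,
    "length_of_stay": 0.02,
}

#: probabilities of carrying each exclusion-criterion feature
DEFAULT_EXCLUSION_RATES: Mapping[str, float] = {
    "age_over_80": 0.15,
    "asa_class_3": 0.07,
    "septic": 0.02,
    "secondary": 0.16,
    "revision": 0.09,
}


@dataclass
class SimulationConfig:
    """Full specification of one synthetic cohort draw."""

    n: int = 1600
    seed: int = 0
    marginals: CovariateMarginals = field(default_factory=CovariateMarginals)
    beta_treat: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETA_TREAT))
    gamma_physical: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GAMMA_PHYSICAL))
    gamma_mental: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GAMMA_MENTAL))
    tau_physical: float = 2.0
    tau_mental: float = 0.0
    sigma_out: float = 6.0
    missing_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    exclusion_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSION_RATES))

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigError("n must be positive")
        if self.sigma_out < 0:
            raise ConfigError("sigma_out must be non-negative")
        for name, rates in (("missing_rates", self.missing_rates),
                            ("exclusion_rates", self.exclusion_rates)):
            for k, v in rates.items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"{name}[{k!r}]={v} outside [0, 1]")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    propensity: np.ndarray          # true P(fast_track | x), per patient
    eta_treat: np.ndarray           # true assignment linear predictor
    tau_physical: float
    tau_mental: float
    beta_treat: dict[str, float]
    gamma_physical: dict[str, float]
    gamma_mental: dict[str, float]
    centers: dict[str, float]       # means used to center continuous terms
    treated_fraction: float


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent per-field stream: global seed + CRC32 of the field name."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def _tnorm(rng: np.random.Generator, mean: float, sd: float,
           lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _linear_predictor(coefs: Mapping[str, float], df: pd.DataFrame,
                      centers: Mapping[str, float]) -> np.ndarray:
    eta = np.full(len(df), float(coefs.get("intercept", 0.0)))
    for term, b in coefs.items():
        if term == "intercept" or b == 0.0:
            continue
        if "=" in term:
            name, level = term.split("=", 1)
            if level == "True":
                x = df[name].astype(bool).to_numpy().astype(float)
            else:
                col = df[name]
                lv: object = level
                if name == "asa_class":
                    lv = int(level)
                x = (col == lv).to_numpy().astype(float)
        else:
            x = df[term].to_numpy(dtype=float) - centers[term]
        eta = eta + b * x
    return eta


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Draw one cohort and return it together with its generative ground truth.

    The outcome model is ``post = pre + gamma.x + tau*T + N(0, sigma)``
    with scores clipped to the SF-12 range [0, 80]; missingness is MCAR
    per ``missing_rates`` and is applied after outcomes are generated.
    Identical configs (including seed) yield identical cohorts.
    """
    m = config.marginals
    n = config.n
    seed = config.seed

    age_elderly = _stream(seed, "age_mix").random(n) < config.exclusion_rates["age_over_80"]
    rng_age = _stream(seed, "age")
    age = np.where(
        age_elderly,
        _tnorm(rng_age, m.age_mean, m.age_sd, 80.0 + 1e-9, m.age_max, n),
        _tnorm(rng_age, m.age_mean, m.age_sd, m.age_min, 80.0, n),
    )
    bmi = _tnorm(_stream(seed, "bmi"), m.bmi_mean, m.bmi_sd, m.bmi_min, m.bmi_max, n)
    surgery = _tnorm(_stream(seed, "length_of_surgery"), m.surgery_mean,
                     m.surgery_sd, m.surgery_min, m.surgery_max, n)
    stay = _tnorm(_stream(seed, "length_of_stay"), m.stay_mean, m.stay_sd,
                  m.stay_min, m.stay_max, n)
    phys_pre = _tnorm(_stream(seed, "sf12_physical_pre"), m.physical_pre_mean,
                      m.physical_pre_sd, 0.0, 80.0, n)
    ment_pre = _tnorm(_stream(seed, "sf12_mental_pre"), m.mental_pre_mean,
                      m.mental_pre_sd, 0.0, 80.0, n)

    sex = np.where(_stream(seed, "sex").random(n) < m.p_female, "female", "male")
    oor = _stream(seed, "out_of_region").random(n) < m.p_out_of_region
    site = np.where(_stream(seed, "site").random(n) < m.p_knee, "knee", "hip")
    septic = _stream(seed, "septic").random(n) < config.exclusion_rates["septic"]
    pathology = np.where(
        _stream(seed, "pathology").random(n) < config.exclusion_rates["secondary"],
        "secondary", "primary")
    intervention = np.where(
        _stream(seed, "intervention").random(n) < config.exclusion_rates["revision"],
        "revision", "first")
    asa3 = _stream(seed, "asa3").random(n) < config.exclusion_rates["asa_class_3"]
    asa12 = np.where(_stream(seed, "asa12").random(n) < m.p_asa1_given_eligible, 1, 2)
    asa = np.where(asa3, 3, asa12).astype(float)

    df = pd.DataFrame({
        "patient_id": [f"P{i:05d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "bmi": bmi,
        "out_of_region": oor,
        "asa_class": asa,
        "site": site,
        "pathology": pathology,
        "intervention": intervention,
        "septic": septic,
        "length_of_surgery": surgery,
        "length_of_stay": stay,
        "sf12_physical_pre": phys_pre,
        "sf12_mental_pre": ment_pre,
    })

    centers = {
        "age": m.age_mean,
        "bmi": m.bmi_mean,
        "length_of_surgery": m.surgery_mean,
        "length_of_stay": m.stay_mean,
        "sf12_physical_pre": m.physical_pre_mean,
        "sf12_mental_pre": m.mental_pre_mean,
    }
    eta = _linear_predictor(config.beta_treat, df, centers)
    prop = expit(eta)
    treated = _stream(seed, "treatment").random(n) < prop
    df["fast_track"] = treated

    t = treated.astype(float)
    dphys = (_linear_predictor(config.gamma_physical, df, centers)
             + config.tau_physical * t
             + _stream(seed, "noise_physical").normal(0.0, config.sigma_out, n))
    dment = (_linear_predictor(config.gamma_mental, df, centers)
             + config.tau_mental * t
             + _stream(seed, "noise_mental").normal(0.0, config.sigma_out, n))
    df["sf12_physical_3m"] = np.clip(phys_pre + dphys, 0.0, 80.0)
    df["sf12_mental_3m"] = np.clip(ment_pre + dment, 0.0, 80.0)

    for col, rate in config.missing_rates.items():
        if rate > 0:
            drop = _stream(seed, f"missing_{col}").random(n) < rate
            df.loc[drop, col] = np.nan

    from .data_model import SCHEMA_FIELDS
    df = df[list(SCHEMA_FIELDS)]
    cohort = Cohort(df, filter_log=[],
                    missing_counts={c: int(df[c].isna().sum())
                                    for c in SCHEMA_FIELDS[1:]})
    truth = GroundTruth(
        propensity=prop,
        eta_treat=eta,
        tau_physical=config.tau_physical,
        tau_mental=config.tau_mental,
        beta_treat=dict(config.beta_treat),
        gamma_physical=dict(config.gamma_physical),
        gamma_mental=dict(config.gamma_mental),
        centers=centers,
        treated_fraction=float(treated.mean()),
    )
    return cohort, truth


def simulate_null_improvement(
    n_pairs: int,
    p_both: float,
    p_t_only: float,
    p_c_only: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a paired improvement table for matched (treated, control) pairs.

    Each pair falls in one of four cells (both improved / treated only /
    control only / neither) with the given probabilities; the remainder
    probability goes to "neither".  Returns one row per pair with boolean
    columns ``improved_t`` and ``improved_c``.
    """
    if n_pairs < 0:
        raise ConfigError("n_pairs must be non-negative")
    probs = (p_both, p_t_only, p_c_only)
    if any(p < 0 for p in probs) or sum(probs) > 1.0 + 1e-12:
        raise ConfigError("cell probabilities must be non-negative and sum to <= 1")
    if n_pairs == 0:
        return pd.DataFrame({"improved_t": pd.Series(dtype=bool),
                             "improved_c": pd.Series(dtype=bool)})
    rng = _stream(seed, "null_improvement")
    cells = [p_both, p_t_only, p_c_only, 1.0 - sum(probs)]
    counts = rng.multinomial(n_pairs, cells)
    flags = [(True, True), (True, False), (False, True), (False, False)]
    t_flags: list[bool] = []
    c_flags: list[bool] = []
    for (ft, fc), k in zip(flags, counts):
        t_flags.extend([ft] * int(k))
        c_flags.extend([fc] * int(k))
    return pd.DataFrame({"improved_t": t_flags, "improved_c": c_flags})
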
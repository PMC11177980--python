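"""Synthetic chest-pain cohort generator.

The study's real EMS registry is private, so this module generates cohorts
with the statistical structure the downstream analysis assumes:

* covariate marginals matching the published internal (n=1756) and external
  (n=1127) cohort tables — including the distribution shift between them
  (e.g. hypertension 53% internal vs 71% external);
* a latent linear risk score ``s = intercept + sum(coef_j * x_j)`` mapped
  through the logistic link to P(ACS), with the intercept calibrated by
  bisection on a large pilot sample so the marginal ACS prevalence hits the
  configured target (20% by default);
* ACS subtypes (STEMI / NSTEMI / UA) drawn from a configurable split,
  defaulting to (0.65, 0.20, 0.15) given ACS so the marginal prevalences
  land near the published 14% STEMI / 7% NSTE-ACS;
* per-lead ECG interpretation vectors: any-lead positivity at the published
  rate, number of positive leads from a truncated geometric on {1..11},
  positive leads placed uniformly at random;
* completely-at-random missingness: a patient is selected with probability
  ``missingness_rate`` (default 1.5%, under the study's 2% bound) and one
  uniformly chosen scalar covariate is blanked.

Covariates are conditionally independent given the latent score; real
comorbidity correlations are not emulated (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort import Cohort
from .exceptions import ConfigurationError
from .schema import DEFAULT_SCHEMA, ECG_LEAD_COUNT

AGE_MIN = 21.0  # enrolment criterion: adults over 21
PILOT_SIZE = 200_000
PILOT_SEED = 987_654_321  # fixed so calibration is independent of cohort seed
_INTERCEPT_RANGE = (-40.0, 40.0)

#: per-covariate Bernoulli rates (and age moments) for the two cohorts.
#: ECG entries are ANY-lead positivity rates; ``(+/-31)`` printed for age is
#: read as mean +/- 2 SD, hence SD 15.5.
INTERNAL_MARGINALS: dict[str, float] = {
    "age_mean": 61.0, "age_sd": 15.5,
    "gender_male": 0.53,
    "hypercholesterolemia": 0.39, "hypertension": 0.53, "current_smoker": 0.20,
    "diabetes": 0.28, "prior_mi": 0.17, "angina": 0.02, "prior_cabg": 0.09,
    "prior_pci": 0.07, "cad": 0.19, "family_history_cv": 0.11,
    "sym_other": 0.99, "sym_chest_pain": 0.56, "sym_syncope": 0.05,
    "sym_shortness_of_breath": 0.23, "sym_diaphoresis": 0.06,
    "sym_nausea_vomiting": 0.09, "sym_palpitations": 0.12,
    "sym_other_symptoms": 0.49,
    "ecg_st_elevation": 0.18, "ecg_st_depression": 0.28,
    "ecg_t_wave_inversion": 0.14,
}

EXTERNAL_MARGINALS: dict[str, float] = {
    "age_mean": 60.0, "age_sd": 15.5,
    "gender_male": 0.55,
    "hypercholesterolemia": 0.43, "hypertension": 0.71, "current_smoker": 0.25,
    "diabetes": 0.31, "prior_mi": 0.21, "angina": 0.07, "prior_cabg": 0.15,
    "prior_pci": 0.005, "cad": 0.24, "family_history_cv": 0.07,
    "sym_other": 0.99, "sym_chest_pain": 0.57, "sym_syncope": 0.06,
    "sym_shortness_of_breath": 0.25, "sym_diaphoresis": 0.07,
    "sym_nausea_vomiting": 0.10, "sym_palpitations": 0.14,
    "sym_other_symptoms": 0.54,
    "ecg_st_elevation": 0.15, "ecg_st_depression": 0.19,
    "ecg_t_wave_inversion": 0.15,
}

#: log-odds contributions to the latent risk score.  ECG coefficients apply
#: per positive lead; the age coefficient applies per year, centred at the
#: preset mean.  ST elevation carries the strongest weight, with moderate
#: weight on ST depression, chest pain and cardiac history; the near-universal
#: "other" symptom and palpitations carry none.  The scale is a modelling
#: choice targeting strong but imperfect separability (oracle AUROC ~0.93).
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "age": 0.055, "gender_male": 0.6,
    "hypercholesterolemia": 0.5, "hypertension": 0.5, "current_smoker": 0.6,
    "diabetes": 0.6, "prior_mi": 1.0, "angina": 0.8, "prior_cabg": 0.6,
    "prior_pci": 0.6, "cad": 1.0, "family_history_cv": 0.4,
    "sym_other": 0.0, "sym_chest_pain": 1.4, "sym_syncope": 0.2,
    "sym_shortness_of_breath": 0.4, "sym_diaphoresis": 0.8,
    "sym_nausea_vomiting": 0.6, "sym_palpitations": 0.0,
    "sym_other_symptoms": 0.0,
    "ecg_st_elevation": 2.2, "ecg_st_depression": 0.9,
    "ecg_t_wave_inversion": 0.5,
}

DEFAULT_SUBTYPE_SPLIT = (0.65, 0.20, 0.15)  # (STEMI, NSTEMI, UA) given ACS
DEFAULT_N_INTERNAL = 1756
DEFAULT_N_EXTERNAL = 1127


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of one synthetic cohort draw."""

    n: int = DEFAULT_N_INTERNAL
    seed: int = 0
    tag: str = "internal"
    acs_prevalence: float = 0.20
    subtype_split: tuple[float, float, float] = DEFAULT_SUBTYPE_SPLIT
    covariate_marginals: dict[str, float] = field(
        default_factory=lambda: dict(INTERNAL_MARGINALS)
    )
    effect_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    ecg_lead_geom_p: float = 0.45
    missingness_rate: float = 0.015
    troponin_given_acs: tuple[float, float, float] = (0.15, 0.35, 0.50)
    troponin_given_no_acs: tuple[float, float, float] = (0.85, 0.12, 0.03)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigurationError("n must be positive")
        probs = [self.acs_prevalence, self.missingness_rate, self.ecg_lead_geom_p,
                 *self.subtype_split, *self.troponin_given_acs,
                 *self.troponin_given_no_acs]
        probs += [v for k, v in self.covariate_marginals.items()
                  if not k.startswith("age_")]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        for split in (self.subtype_split, self.troponin_given_acs,
                      self.troponin_given_no_acs):
            if abs(sum(split) - 1.0) > 1e-9:
                raise ConfigurationError(f"probabilities {split} do not sum to 1")


def internal_config(n: int = DEFAULT_N_INTERNAL, seed: int = 0, **kw) -> GeneratorConfig:
    """Default configuration emulating the internal (development) cohort."""
    return GeneratorConfig(n=n, seed=seed, tag="internal",
                           covariate_marginals=dict(INTERNAL_MARGINALS), **kw)


def external_config(n: int = DEFAULT_N_EXTERNAL, seed: int = 1, **kw) -> GeneratorConfig:
    """Default configuration for the temporally shifted external cohort."""
    return GeneratorConfig(n=n, seed=seed, tag="external",
                           covariate_marginals=dict(EXTERNAL_MARGINALS), **kw)


# ---------------------------------------------------------------------------
# covariate sampling


def _truncated_geometric_pmf(p: float) -> np.ndarray:
    k = np.arange(1, ECG_LEAD_COUNT + 1)
    pmf = (1.0 - p) ** (k - 1) * p
    return pmf / pmf.sum()


def _draw_covariates(rng: np.random.Generator, config: GeneratorConfig,
                     n: int) -> pd.DataFrame:
    m = config.covariate_marginals
    schema = DEFAULT_SCHEMA
    a = (AGE_MIN - m["age_mean"]) / m["age_sd"]
    age = truncnorm.rvs(a, np.inf, loc=m["age_mean"], scale=m["age_sd"],
                        size=n, random_state=rng)
    data: dict[str, np.ndarray] = {"age": age}
    for name in schema.names("baseline")[1:] + schema.names("history") + schema.names("symptom"):
        data[name] = (rng.random(n) < m[name]).astype(float)
    pmf = _truncated_geometric_pmf(config.ecg_lead_geom_p)
    for name in schema.names("ecg"):
        any_pos = rng.random(n) < m[name]
        counts = rng.choice(np.arange(1, ECG_LEAD_COUNT + 1), size=n, p=pmf)
        # uniform placement without replacement: rank random draws per row
        ranks = rng.random((n, ECG_LEAD_COUNT)).argsort(axis=1).argsort(axis=1)
        leads = (ranks < counts[:, None]) & any_pos[:, None]
        for j in range(ECG_LEAD_COUNT):
            data[f"{name}_L{j + 1:02d}"] = leads[:, j].astype(float)
    return pd.DataFrame(data)[schema.columns()]


def latent_score(covariates: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    """Latent log-odds score (without intercept) for each row."""
    coef = config.effect_coefficients
    age_mean = config.covariate_marginals["age_mean"]
    s = coef["age"] * (covariates["age"].to_numpy() - age_mean)
    for name in DEFAULT_SCHEMA.names():
        if name == "age":
            continue
        c = coef.get(name, 0.0)
        if c == 0.0:
            continue
        cols = [e for e in DEFAULT_SCHEMA.entries if e.name == name][0].columns
        s = s + c * covariates[cols].to_numpy().sum(axis=1)
    return s


_intercept_cache: dict[tuple, float] = {}


def calibrated_intercept(config: GeneratorConfig) -> float:
    """Intercept giving the target marginal ACS prevalence.

    Bisection on a fixed pilot sample of 200,000 covariate draws; cached on
    the (marginals, coefficients, prevalence) tuple so repeated cohort draws
    reuse the calibration.
    """
    key = (
        tuple(sorted(config.covariate_marginals.items())),
        tuple(sorted(config.effect_coefficients.items())),
        config.acs_prevalence, config.ecg_lead_geom_p,
    )
    if key in _intercept_cache:
        return _intercept_cache[key]
    pilot = _draw_covariates(np.random.default_rng(PILOT_SEED), config, PILOT_SIZE)
    s = latent_score(pilot, config)

    def prevalence_at(b: float) -> float:
        return float(expit(b + s).mean())

    lo, hi = _INTERCEPT_RANGE
    if not (prevalence_at(lo) <= config.acs_prevalence <= prevalence_at(hi)):
        raise ConfigurationError(
            f"target prevalence {config.acs_prevalence} unreachable with the "
            "configured effect coefficients"
        )
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if prevalence_at(mid) < config.acs_prevalence:
            lo = mid
        else:
            hi = mid
    b = 0.5 * (lo + hi)
    _intercept_cache[key] = b
    return b


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw one cohort; deterministic given ``config.seed``.

    Missingness is injected but NOT imputed: downstream code is expected to
    apply :func:`acsselect.cohort.impute_constant` as the pipeline would on
    real data.
    """
    rng = np.random.default_rng(config.seed)
    cov = _draw_covariates(rng, config, config.n)
    b = calibrated_intercept(config)
    p_acs = expit(b + latent_score(cov, config))
    acs = (rng.random(config.n) < p_acs).astype(int)
    subtype = np.full(config.n, "NONE", dtype=object)
    idx = np.flatnonzero(acs)
    if idx.size:
        subtype[idx] = rng.choice(
            np.array(["STEMI", "NSTEMI", "UA"], dtype=object),
            size=idx.size, p=np.asarray(config.subtype_split),
        )
    # missingness: completely at random over the 20 scalar covariates
    scalar_cols = DEFAULT_SCHEMA.scalar_columns
    hit = rng.random(config.n) < config.missingness_rate
    which = rng.integers(0, len(scalar_cols), size=config.n)
    for i in np.flatnonzero(hit):
        cov.iat[i, cov.columns.get_loc(scalar_cols[which[i]])] = np.nan
    labels = pd.DataFrame({"acs": acs, "subtype": subtype})
    return Cohort(cov, labels, tag=config.tag)


def temporal_split_pair(
    config_internal: GeneratorConfig | None = None,
    config_external: GeneratorConfig | None = None,
) -> tuple[Cohort, Cohort]:
    """Independent internal/external cohorts sharing the disease mechanism.

    The two configurations may differ in covariate marginals (distribution
    shift) but must share effect coefficients — the generator models a
    temporal split of one population, not two diseases.
    """
    ci = config_internal if config_internal is not None else internal_config()
    ce = config_external if config_external is not None else external_config()
    if ci.effect_coefficients != ce.effect_coefficients:
        raise ConfigurationError(
            "internal and external configs must share effect_coefficients"
        )
    return generate_cohort(ci), generate_cohort(ce)


def generate_troponin(cohort: Cohort, config: GeneratorConfig) -> Cohort:
    """Attach an ordinal troponin band {0,1,2} correlated with ACS status.

    Bands are drawn from the configured conditional distributions given the
    ACS label.  The band exists only to feed the HEART-score comparator;
    the boosted-tree model never sees it.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    bands = np.arange(3)
    p = np.where(
        cohort.acs[:, None].astype(bool),
        np.asarray(config.troponin_given_acs),
        np.asarray(config.troponin_given_no_acs),
    )
    u = rng.random(len(cohort))
    trop = (u[:, None] > p.cumsum(axis=1)).sum(axis=1)
    trop = np.minimum(trop, bands[-1])
    return replace(cohort, troponin=pd.Series(trop, name="troponin_band"))
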
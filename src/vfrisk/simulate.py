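"""Synthetic multi-survey woman-level datasets with known ground truth.

Emulates the structure of pooled DHS/MICS-style household surveys of women
aged 15-49: 20-30 surveys with multistage-cluster sampling weights, a rare
binary outcome (vaginal fistula symptoms, ~1-3 per 1,000), imperfect
self-report (sensitivity ~95-99.9%, specificity ~99.85-99.95%), per-survey
outcome eligibility restrictions, and the covariates and exposures used in
the pooled risk-factor analysis (age, literacy, residence, religion,
gravidity, FGM, IPSV, stature, ages at first sex/birth, permission to seek
care).

The generator knows the true outcome status of every woman (``vf_true``),
so every downstream stage — harmonization, matching, misclassification-
adjusted regression — can be validated against known effect sizes without
access to the restricted-access microdata the design mimics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from scipy.special import expit, logit

__all__ = [
    "SimulationConfig",
    "WOMAN_COLUMNS",
    "GUARDED_FIELDS",
    "simulate_population",
    "apply_misclassification",
    "inject_missingness",
    "write_women_csv",
    "read_women_csv",
]

#: Fixed column order of a woman-level table (one row per survey respondent).
WOMAN_COLUMNS = [
    "survey_id",
    "country",
    "cluster_id",
    "sampling_weight",
    "dv_weight",
    "age_years",
    "literate",
    "post_primary",
    "height_cm",
    "fgm",
    "ipsv",
    "age_first_sex_years",
    "age_first_birth_years",
    "permission_problem",
    "residence",
    "religion",
    "gravid",
    "ever_married",
    "vf_reported",
    "vf_true",
]

#: Survey-design and provenance fields that may never be masked as missing.
GUARDED_FIELDS = {
    "survey_id",
    "country",
    "cluster_id",
    "sampling_weight",
    "dv_weight",
    "vf_reported",
    "vf_true",
}

_BOOL_COLUMNS = [
    "literate",
    "post_primary",
    "fgm",
    "ipsv",
    "gravid",
    "ever_married",
    "vf_reported",
    "vf_true",
]

_EXPOSURE_FIELDS = (
    "fgm",
    "ipsv",
    "short_stature",
    "young_first_sex",
    "young_first_birth",
    "permission_problem",
    "illiterate",
)

_ELIGIBILITY_MODES = ("all_women", "ever_married", "ever_pregnant", "recent_birth")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic survey world.

    The outcome-generating model is a logistic regression on the true
    (latent) outcome::

        logit P(vf_true = 1) = alpha_true
                               + beta_exposure_true * exposed
                               + sum_c beta_covariates_true[c] * x_c

    followed by non-differential misclassification of the self-report with
    ``sensitivity_true`` and ``specificity_true``. Defaults reproduce the
    pooled-survey conditions the pipeline is designed for: 24 surveys, a
    marginal true-outcome prevalence near 2-3 per 1,000 (``alpha_true = -6.9``
    plus covariate effects), a
    focal exposure with odds ratio 2, and self-report accuracy at the
    centres of the prior supports used by the inference model
    (Se = 0.975, Sp = 0.999).
    """

    n_surveys: int = 24
    women_per_survey: int = 12_000
    clusters_per_survey: int = 50
    weight_dispersion: float = 0.3
    alpha_true: float = -6.9
    beta_exposure_true: float = float(np.log(2.0))
    beta_covariates_true: dict[str, float] = field(
        default_factory=lambda: {
            "age_std": 0.3,
            "literate": -0.3,
            "gravid": 0.7,
            "urban": -0.2,
        }
    )
    exposure_field: str = "fgm"
    exposure_prevalence: float = 0.42
    sensitivity_true: float = 0.975
    specificity_true: float = 0.999
    missing_rate: dict[str, float] = field(
        default_factory=lambda: {
            "height_cm": 0.02,
            "literate": 0.005,
            "post_primary": 0.005,
            "fgm": 0.005,
            "ipsv": 0.005,
            "age_first_sex_years": 0.04,
            "age_first_birth_years": 0.005,
            "permission_problem": 0.005,
            "gravid": 0.005,
        }
    )
    #: log-odds of exposure per unit of (age-30)/10 and for literacy — mild
    #: confounding so matching and covariate adjustment have real work to do.
    confounding_age: float = 0.3
    confounding_literacy: float = 0.3
    #: fraction of parous women whose age-at-first-sex answer contradicts
    #: their birth history ("never had intercourse" yet a birth on record).
    inconsistent_sex_rate: float = 0.02
    eligibility_mode: str = "all_women"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surveys <= 0 or self.women_per_survey <= 0:
            raise ValueError("n_surveys and women_per_survey must be positive")
        if self.clusters_per_survey <= 0:
            raise ValueError("clusters_per_survey must be positive")
        if self.weight_dispersion < 0:
            raise ValueError("weight_dispersion must be >= 0")
        if not 0.0 < self.exposure_prevalence < 1.0:
            raise ValueError("exposure_prevalence must lie in (0, 1)")
        for name, value in (
            ("sensitivity_true", self.sensitivity_true),
            ("specificity_true", self.specificity_true),
        ):
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        for fname, rate in self.missing_rate.items():
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"missing rate for {fname!r} must lie in [0, 1)")
        if self.exposure_field not in _EXPOSURE_FIELDS:
            raise ValueError(
                f"unknown exposure_field {self.exposure_field!r}; "
                f"expected one of {_EXPOSURE_FIELDS}"
            )
        if self.eligibility_mode not in _ELIGIBILITY_MODES:
            raise ValueError(
                f"unknown eligibility_mode {self.eligibility_mode!r}; "
                f"expected one of {_ELIGIBILITY_MODES}"
            )
        if not np.isfinite(self.alpha_true) or not np.isfinite(self.beta_exposure_true):
            raise ValueError("non-finite linear predictor coefficients")
        for name, value in self.beta_covariates_true.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite coefficient for covariate {name!r}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def apply_misclassification(truth, se: float, sp: float, seed: int):
    """Misclassify a boolean sequence non-differentially.

    Each true positive is reported positive with probability ``se``; each
    true negative is reported positive with probability ``1 - sp``,
    independently across subjects.
    """
    if not 0.0 < se <= 1.0 or not 0.0 < sp <= 1.0:
        raise ValueError("se and sp must lie in (0, 1]")
    truth = np.asarray(truth, dtype=bool)
    if truth.size == 0:
        return truth.copy()
    rng = np.random.default_rng(seed)
    u = rng.random(truth.shape)
    return np.where(truth, u < se, u < (1.0 - sp))


def inject_missingness(records: pd.DataFrame, rates: dict[str, float], seed: int) -> pd.DataFrame:
    """Set fields missing completely at random at per-field rates.

    Survey-design fields and the latent truth column are guarded and may
    not be masked; requesting them raises a ``ValueError`` naming the field.
    """
    for name, rate in rates.items():
        if name in GUARDED_FIELDS:
            raise ValueError(f"field {name!r} is a design/provenance field and cannot be masked")
        if name not in records.columns:
            raise ValueError(f"unknown field {name!r}")
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"missing rate for {name!r} must lie in [0, 1)")
    out = records.copy()
    rng = np.random.default_rng(seed)
    # iterate in fixed column order so output is seed-deterministic
    for name in records.columns:
        rate = rates.get(name)
        if not rate:
            continue
        mask = rng.random(len(out)) < rate
        out.loc[mask, name] = pd.NA
    return out


def _draw_confounded_bernoulli(rng, target_prev, age_std, literate, c_age, c_lit, n):
    """Bernoulli draw with logistic dependence on age and literacy, centred
    so the marginal prevalence stays at ``target_prev``."""
    lit = np.asarray(literate, dtype=float)
    lin = c_age * age_std + c_lit * lit
    lin = lin - lin.mean()
    eta0 = logit(target_prev)
    # one Newton step on the intercept keeps the marginal close to target
    for _ in range(3):
        p = expit(eta0 + lin)
        m = p.mean()
        grad = np.mean(p * (1 - p))
        if grad <= 0:
            break
        eta0 -= (m - target_prev) / grad
    p = expit(eta0 + lin)
    return rng.random(n) < p


def simulate_population(config: SimulationConfig) -> pd.DataFrame:
    """Generate the pooled woman-level table for all surveys.

    Returns a DataFrame with one row per woman and the fixed
    :data:`WOMAN_COLUMNS` order. The same config (including its seed)
    always yields an identical table.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_surveys * config.women_per_survey

    survey_idx = np.repeat(np.arange(config.n_surveys), config.women_per_survey)
    survey_id = np.array([f"S{i + 1:02d}" for i in range(config.n_surveys)])[survey_idx]
    country = np.array([f"C{i + 1:02d}" for i in range(config.n_surveys)])[survey_idx]
    cluster = rng.integers(1, config.clusters_per_survey + 1, size=n_total)
    cluster_id = np.char.add(
        np.char.add(survey_id.astype(str), "-K"), cluster.astype(str)
    )

    # sampling weights: log-normal, mean-normalised within survey
    w = rng.lognormal(mean=0.0, sigma=config.weight_dispersion, size=n_total)
    w_frame = pd.Series(w).groupby(survey_idx).transform("mean")
    sampling_weight = w / w_frame.to_numpy()

    # age pyramid: linearly decreasing 15 -> 49
    ages = np.arange(15, 50)
    age_probs = np.linspace(1.0, 0.55, ages.size)
    age_probs /= age_probs.sum()
    age_years = rng.choice(ages, size=n_total, p=age_probs)
    age_std = (age_years - 30.0) / 10.0

    urban = rng.random(n_total) < 0.35
    literate = rng.random(n_total) < expit(-0.2 + 0.8 * urban - 0.3 * age_std)
    post_primary = rng.random(n_total) < np.where(literate, 0.55, 0.05)
    religion = rng.choice(
        np.array(["christian", "muslim", "other"]),
        size=n_total,
        p=[0.55, 0.35, 0.10],
    )
    ever_married = rng.random(n_total) < expit(-8.0 + 0.4 * age_years)
    gravid = rng.random(n_total) < expit(-7.0 + 0.35 * age_years)
    parous = gravid & (rng.random(n_total) < 0.9)

    # ages at first birth / first sex (integer years, consistent with age)
    afb = np.round(rng.normal(18.5, 3.0, size=n_total)).astype(int)
    afb = np.clip(afb, 11, np.maximum(age_years, 11))
    sexually_active = ever_married | gravid | (rng.random(n_total) < expit(0.2 * (age_years - 18)))
    afs = np.round(rng.normal(16.5, 2.5, size=n_total)).astype(int)
    afs = np.clip(afs, 10, np.maximum(age_years, 10))
    afs = np.minimum(afs, np.where(parous, afb, afs))

    height = rng.normal(158.0, 5.9, size=n_total)

    fgm = _draw_confounded_bernoulli(
        rng, 0.42, age_std, literate, config.confounding_age, -config.confounding_literacy, n_total
    )
    ipsv = np.zeros(n_total, dtype=bool)
    ipsv[ever_married] = rng.random(int(ever_married.sum())) < 0.09
    permission = rng.random(n_total) < 0.18

    # focal exposure overrides the matching field, drawn at the configured
    # prevalence with the configured confounding
    exp_field = config.exposure_field
    if exp_field in ("fgm", "ipsv", "permission_problem", "illiterate"):
        eligible = ever_married if exp_field == "ipsv" else np.ones(n_total, dtype=bool)
    elif exp_field == "young_first_sex":
        eligible = sexually_active
    elif exp_field == "young_first_birth":
        eligible = parous
    else:  # short_stature
        eligible = np.ones(n_total, dtype=bool)

    n_elig = int(eligible.sum())
    exposed = np.zeros(n_total, dtype=bool)
    exposed[eligible] = _draw_confounded_bernoulli(
        rng,
        config.exposure_prevalence,
        age_std[eligible],
        literate[eligible],
        config.confounding_age,
        config.confounding_literacy,
        n_elig,
    )

    if exp_field == "fgm":
        fgm = exposed
    elif exp_field == "ipsv":
        ipsv = exposed
    elif exp_field == "permission_problem":
        permission = exposed
    elif exp_field == "illiterate":
        literate = ~exposed
    elif exp_field == "short_stature":
        short = rng.uniform(140.0, 149.9, size=n_total)
        tall = rng.uniform(150.0, 176.0, size=n_total)
        height = np.where(exposed, short, tall)
    elif exp_field == "young_first_sex":
        afs = np.where(exposed, rng.integers(10, 14, size=n_total), np.maximum(afs, 14))
        afs = np.clip(afs, 10, np.maximum(age_years, 10))
    elif exp_field == "young_first_birth":
        afb = np.where(exposed, rng.integers(11, 14, size=n_total), np.maximum(afb, 14))
        afb = np.clip(afb, 11, np.maximum(age_years, 11))

    # true outcome from the generating logistic model
    covariate_cols = {
        "age_std": age_std,
        "literate": literate.astype(float),
        "gravid": gravid.astype(float),
        "urban": urban.astype(float),
        "post_primary": post_primary.astype(float),
    }
    eta = config.alpha_true + config.beta_exposure_true * exposed.astype(float)
    for name, coef in config.beta_covariates_true.items():
        if name not in covariate_cols:
            raise ValueError(f"unknown covariate {name!r} in beta_covariates_true")
        eta = eta + coef * covariate_cols[name]
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor; check configured coefficients")
    vf_true = rng.random(n_total) < expit(eta)

    vf_reported = apply_misclassification(
        vf_true,
        config.sensitivity_true,
        config.specificity_true,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    # outcome-question eligibility (some surveys restrict who is asked)
    if config.eligibility_mode == "ever_married":
        asked = ever_married
    elif config.eligibility_mode == "ever_pregnant":
        asked = gravid
    elif config.eligibility_mode == "recent_birth":
        asked = parous & ((age_years - afb) <= 5)
    else:
        asked = np.ones(n_total, dtype=bool)

    # domestic-violence module weight: perturbed sampling weight, present
    # only for the ever-married (IPSV-eligible) subsample
    dv = sampling_weight * rng.lognormal(0.0, 0.1, size=n_total)

    df = pd.DataFrame(
        {
            "survey_id": survey_id,
            "country": country,
            "cluster_id": cluster_id,
            "sampling_weight": sampling_weight,
            "dv_weight": dv,
            "age_years": age_years,
            "literate": literate,
            "post_primary": post_primary,
            "height_cm": height,
            "fgm": fgm,
            "ipsv": ipsv,
            "age_first_sex_years": afs.astype(object),
            "age_first_birth_years": afb.astype(float),
            "permission_problem": np.where(permission, "big_problem", "not_big_problem"),
            "residence": np.where(urban, "urban", "rural"),
            "religion": religion,
            "gravid": gravid,
            "ever_married": ever_married,
            "vf_reported": vf_reported,
            "vf_true": vf_true,
        }
    )
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype("boolean")
    df["age_years"] = df["age_years"].astype("Int64")

    # field-level structure: never-active women have no age at first sex;
    # a small fraction of parous women give the inconsistent "never" answer
    never = ~sexually_active
    df.loc[never, "age_first_sex_years"] = "never"
    incons = parous & (rng.random(n_total) < config.inconsistent_sex_rate)
    df.loc[incons, "age_first_sex_years"] = "never"
    df.loc[~parous, "age_first_birth_years"] = np.nan
    df.loc[~ever_married, "ipsv"] = pd.NA
    df.loc[~ever_married, "dv_weight"] = np.nan
    df.loc[~asked, "vf_reported"] = pd.NA

    df = inject_missingness(
        df, config.missing_rate, seed=int(rng.integers(0, 2**31 - 1))
    )
    return df[WOMAN_COLUMNS]


def write_women_csv(df: pd.DataFrame, path) -> None:
    """Write a woman-level table: booleans as 0/1, missing as empty string."""
    out = df.copy()
    for col in _BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype("Int64")
    out.to_csv(path, index=False, na_rep="")


def read_women_csv(path) -> pd.DataFrame:
    """Read a woman-level CSV written by :func:`write_women_csv`."""
    df = pd.read_csv(
        path,
        dtype={
            "survey_id": "string",
            "country": "string",
            "cluster_id": "string",
            "age_first_sex_years": "object",
            "permission_problem": "string",
            "residence": "string",
            "religion": "string",
        },
        keep_default_na=True,
    )
    for col in _BOOL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype("Int64").astype("boolean")
    if "age_years" in df.columns:
        df["age_years"] = df["age_years"].astype("Int64")

    def _coerce_afs(v):
        if pd.isna(v):
            return pd.NA
        s = str(v)
        if s in ("never", "inconsistent"):
            return s
        return int(float(s))

    if "age_first_sex_years" in df.columns:
        df["age_first_sex_years"] = df["age_first_sex_years"].map(_coerce_afs)
    return df
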
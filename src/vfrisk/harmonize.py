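"""Exposure coding, eligibility, cleaning, and pooling of survey records.

Implements the harmonization rules of the pooled analysis:

* literacy is ascertained from a sentence-reading test, with post-primary
  schooling taken as de-facto literacy when the test is absent;
* continuous exposures are dichotomized with strict thresholds
  (height < 150 cm; age at first sex < 14; age at first birth < 14);
* inconsistent age-at-first-sex answers (never had intercourse yet a birth
  on record) are treated as missing;
* surveys lacking gravidity impute it from parity (all nulliparous women
  assumed nulligravid); surveys lacking religion carry a missing-indicator
  category;
* per-factor eligibility (ever-married for IPSV, sexually active for age at
  first sex, parous for age at first birth) restricts the pooled table, and
  rows with any missing exposure/covariate/outcome are dropped (religion
  excepted via its missing category).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import yaml

__all__ = [
    "ExposureSpec",
    "FACTORS",
    "derive_literacy",
    "dichotomize",
    "clean_age_first_sex",
    "apply_survey_defaults",
    "build_analysis_table",
    "age_group",
    "read_survey_meta",
]

CODING_RULES = (
    "short_stature",
    "young_first_sex",
    "young_first_birth",
    "permission_problem",
    "fgm",
    "ipsv",
    "post_primary",
    "literate",
)

ELIGIBILITIES = ("all_women", "ever_married", "sexually_active", "parous")

#: covariates adjusted for in the outcome regressions (age is binned after
#: matching on continuous age; religion keeps its own missing category)
DEFAULT_ADJUSTMENT = ("age_group", "literate", "gravid", "urban", "religion")


@dataclass(frozen=True)
class ExposureSpec:
    """Per-risk-factor eligibility, coding, matching, and adjustment rules."""

    name: str
    coding_rule: str
    eligibility: str = "all_women"
    match_ratio: int = 1
    exact_on_survey: bool = False
    weight_field: str = "sampling_weight"
    adjustment_set: tuple[str, ...] = DEFAULT_ADJUSTMENT
    include_country_effects: bool = True

    def __post_init__(self):
        if self.match_ratio < 1:
            raise ValueError("match_ratio must be >= 1")
        if self.coding_rule not in CODING_RULES:
            raise ValueError(f"unknown coding rule {self.coding_rule!r}")
        if self.eligibility not in ELIGIBILITIES:
            raise ValueError(f"unknown eligibility {self.eligibility!r}")
        if self.weight_field not in ("sampling_weight", "dv_weight"):
            raise ValueError("weight_field must be sampling_weight or dv_weight")
        if self.coding_rule in ("literate", "post_primary") and "literate" in self.adjustment_set:
            raise ValueError("literacy exposures must not adjust for literacy")
        if self.coding_rule == "young_first_birth" and "gravid" in self.adjustment_set:
            raise ValueError("age-at-first-birth must not adjust for gravidity")


def _without(adjustment, *names):
    return tuple(c for c in adjustment if c not in names)


#: The eight risk factors of the pooled analysis, with the matching ratios,
#: exact-on-survey constraints, weight sources, eligibility restrictions and
#: adjustment sets used for each.
FACTORS: dict[str, ExposureSpec] = {
    "literacy": ExposureSpec(
        name="literacy",
        coding_rule="literate",
        match_ratio=1,
        adjustment_set=_without(DEFAULT_ADJUSTMENT, "literate"),
    ),
    "post_primary": ExposureSpec(
        name="post_primary",
        coding_rule="post_primary",
        match_ratio=1,
        adjustment_set=_without(DEFAULT_ADJUSTMENT, "literate"),
    ),
    "fgm": ExposureSpec(name="fgm", coding_rule="fgm", match_ratio=1),
    "short_stature": ExposureSpec(
        name="short_stature",
        coding_rule="short_stature",
        match_ratio=4,
        exact_on_survey=True,
    ),
    "ipsv": ExposureSpec(
        name="ipsv",
        coding_rule="ipsv",
        eligibility="ever_married",
        match_ratio=2,
        exact_on_survey=True,
        weight_field="dv_weight",
    ),
    "young_first_sex": ExposureSpec(
        name="young_first_sex",
        coding_rule="young_first_sex",
        eligibility="sexually_active",
        match_ratio=3,
        exact_on_survey=True,
    ),
    "young_first_birth": ExposureSpec(
        name="young_first_birth",
        coding_rule="young_first_birth",
        eligibility="parous",
        match_ratio=8,
        exact_on_survey=True,
        adjustment_set=_without(DEFAULT_ADJUSTMENT, "gravid"),
        include_country_effects=False,
    ),
    "permission": ExposureSpec(
        name="permission",
        coding_rule="permission_problem",
        match_ratio=1,
        exact_on_survey=True,
        include_country_effects=False,
    ),
}


def derive_literacy(reading_test, post_primary):
    """Literacy from the sentence-reading test and schooling level.

    A woman is literate iff she read the full sentence, or reported some
    secondary education or higher (de-facto literate). Reading only part of
    the sentence counts as not literate. With neither field available the
    result is missing.

    Parameters
    ----------
    reading_test : {"full", "partial", "none"} or missing
    post_primary : bool or missing
    """
    pp = None if pd.isna(post_primary) else bool(post_primary)
    if pp:
        return True
    if reading_test is None or pd.isna(reading_test):
        return pd.NA
    if reading_test not in ("full", "partial", "none"):
        raise ValueError(f"unknown reading test result {reading_test!r}")
    return reading_test == "full"


def clean_age_first_sex(records: pd.DataFrame):
    """Clean the age-at-first-sex field of a woman-level table.

    Returns an object Series holding an integer age, the marker ``"never"``
    for consistent never-active respondents, or missing. A "never had
    intercourse" answer from a woman with a birth on record is an
    inconsistent response and becomes missing.
    """
    afs = records["age_first_sex_years"]
    has_birth = records["age_first_birth_years"].notna()

    def _clean(value, birth):
        if pd.isna(value) or value == "inconsistent":
            return pd.NA
        if value == "never":
            return pd.NA if birth else "never"
        return int(value)

    return pd.Series(
        [_clean(v, b) for v, b in zip(afs, has_birth)],
        index=records.index,
        dtype="object",
    )


def dichotomize(records: pd.DataFrame, rule: str):
    """Code a risk-factor exposure as a nullable boolean Series.

    Thresholds are strict: height < 150 cm, age at first sex < 14 years,
    age at first birth < 14 years. Missing underlying fields yield missing.
    """
    if rule not in CODING_RULES:
        raise ValueError(f"unknown coding rule {rule!r}; expected one of {CODING_RULES}")
    if rule == "short_stature":
        out = (records["height_cm"] < 150.0).astype("boolean").mask(
            records["height_cm"].isna()
        )
    elif rule == "young_first_sex":
        afs = clean_age_first_sex(records)
        out = pd.Series(
            [pd.NA if (pd.isna(v) or v == "never") else v < 14 for v in afs],
            index=records.index,
        )
    elif rule == "young_first_birth":
        out = (records["age_first_birth_years"] < 14).astype("boolean").mask(
            records["age_first_birth_years"].isna()
        )
    elif rule == "permission_problem":
        out = (records["permission_problem"] == "big_problem").astype("boolean").mask(
            records["permission_problem"].isna()
        )
    else:  # direct boolean fields: fgm, ipsv, post_primary, literate
        out = records[rule]
    return out.astype("boolean")


def read_survey_meta(path) -> dict:
    """Load per-survey metadata (YAML): which surveys lack gravidity or
    religion, and each survey's outcome eligibility mode."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def apply_survey_defaults(records: pd.DataFrame, survey_meta: dict) -> pd.DataFrame:
    """Apply survey-level fallbacks for fields some surveys never recorded.

    For surveys flagged without gravidity data, gravidity is imputed from
    parity (every nulliparous woman assumed nulligravid, every parous woman
    gravid). For surveys flagged without religion data, all rows carry the
    explicit ``"missing"`` religion category. Other surveys are untouched,
    so the operation is idempotent.
    """
    out = records.copy()
    for sid, meta in survey_meta.items():
        mask = out["survey_id"] == sid
        if not mask.any():
            continue
        if not meta.get("has_gravidity", True):
            parous = out.loc[mask, "age_first_birth_years"].notna()
            out.loc[mask, "gravid"] = parous.astype("boolean")
        if not meta.get("has_religion", True):
            out.loc[mask, "religion"] = "missing"
    out["religion"] = out["religion"].fillna("missing")
    return out


def age_group(age_years) -> pd.Series:
    """Bin age at interview into the adjustment categories 15-19, 20-29, 30-49."""
    age = pd.Series(age_years)
    out = pd.Series(pd.NA, index=age.index, dtype="object")
    out[(age >= 15) & (age <= 19)] = "15-19"
    out[(age >= 20) & (age <= 29)] = "20-29"
    out[(age >= 30) & (age <= 49)] = "30-49"
    return out


def _eligibility_mask(records: pd.DataFrame, eligibility: str) -> pd.Series:
    if eligibility == "all_women":
        return pd.Series(True, index=records.index)
    if eligibility == "ever_married":
        return records["ever_married"].fillna(False).astype(bool)
    if eligibility == "parous":
        return records["age_first_birth_years"].notna()
    if eligibility == "sexually_active":
        afs = clean_age_first_sex(records)
        return pd.Series(
            [not pd.isna(v) and v != "never" for v in afs], index=records.index
        )
    raise ValueError(f"unknown eligibility {eligibility!r}")


def build_analysis_table(records: pd.DataFrame, spec: ExposureSpec) -> pd.DataFrame:
    """Pool harmonized records into one complete-case analysis table.

    Rows are restricted to the factor's eligible population, the exposure is
    coded by the factor's rule, adjustment covariates are attached (age both
    continuous, for matching, and binned, for regression), and rows with any
    missing exposure, covariate, outcome or weight are dropped — except
    religion, whose missingness is its own category.
    """
    elig = _eligibility_mask(records, spec.eligibility)
    sub = records.loc[elig].copy()

    out = pd.DataFrame(index=sub.index)
    out["survey_id"] = sub["survey_id"]
    out["country"] = sub["country"]
    out["weight"] = sub[spec.weight_field]
    out["age_years"] = sub["age_years"]
    out["exposed"] = dichotomize(sub, spec.coding_rule)
    out["outcome"] = sub["vf_reported"].astype("boolean")
    for cov in spec.adjustment_set:
        if cov == "age_group":
            out["age_group"] = age_group(sub["age_years"])
        elif cov == "urban":
            urb = sub["residence"] == "urban"
            urb[sub["residence"].isna()] = pd.NA
            out["urban"] = urb.astype("boolean")
        elif cov == "religion":
            out["religion"] = sub["religion"].fillna("missing")
        else:
            out[cov] = sub[cov]

    complete = out.notna().all(axis=1)
    out = out.loc[complete]

    n_exposed = int(out["exposed"].sum())
    n_unexposed = int((~out["exposed"].astype(bool)).sum())
    if n_exposed == 0 or n_unexposed == 0:
        raise ValueError(
            f"factor {spec.name!r}: need both exposed and unexposed rows after "
            f"filtering (got {n_exposed} exposed, {n_unexposed} unexposed)"
        )
    out["exposed"] = out["exposed"].astype(bool)
    out["outcome"] = out["outcome"].astype(bool)
    out["age_years"] = out["age_years"].astype(int)
    out["weight"] = out["weight"].astype(float)
    return out
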
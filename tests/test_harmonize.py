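"""Exposure coding, cleaning, eligibility and pooling rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vfrisk import (
    FACTORS,
    apply_survey_defaults,
    build_analysis_table,
    clean_age_first_sex,
    derive_literacy,
    dichotomize,
)
from vfrisk.harmonize import ExposureSpec, age_group


class TestDeriveLiteracy:
    @pytest.mark.parametrize(
        "reading, post_primary, expected",
        [
            ("full", False, True),       # reads full sentence, no schooling
            ("partial", False, False),   # partial reading, primary only
            (None, True, True),          # no test, secondary education
            ("none", False, False),
            ("partial", True, True),     # post-primary overrides the test
            (None, None, pd.NA),         # nothing to go on
            (None, False, pd.NA),        # primary-only without a test result
        ],
    )
    def test_rules(self, reading, post_primary, expected):
        got = derive_literacy(reading, post_primary)
        if expected is pd.NA:
            assert pd.isna(got)
        else:
            assert got == expected

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            derive_literacy("fluent", False)


class TestDichotomize:
    def _frame(self, **cols):
        return pd.DataFrame({k: [v] for k, v in cols.items()})

    @pytest.mark.parametrize(
        "rule, col, value, expected",
        [
            ("short_stature", "height_cm", 149.0, True),
            ("short_stature", "height_cm", 150.0, False),  # strict threshold
            ("short_stature", "height_cm", np.nan, pd.NA),
            ("young_first_birth", "age_first_birth_years", 13.0, True),
            ("young_first_birth", "age_first_birth_years", 14.0, False),
            ("permission_problem", "permission_problem", "big_problem", True),
            ("permission_problem", "permission_problem", "not_big_problem", False),
        ],
    )
    def test_threshold_rules(self, rule, col, value, expected):
        got = dichotomize(self._frame(**{col: value}), rule).iloc[0]
        if expected is pd.NA:
            assert pd.isna(got)
        else:
            assert got == expected

    def test_young_first_sex_uses_cleaned_ages(self):
        df = pd.DataFrame(
            {
                "age_first_sex_years": [13, 14, "never", "never", pd.NA],
                "age_first_birth_years": [np.nan, np.nan, 18.0, np.nan, np.nan],
            }
        )
        got = dichotomize(df, "young_first_sex")
        assert got.iloc[0] == True  # noqa: E712
        assert got.iloc[1] == False  # noqa: E712
        assert pd.isna(got.iloc[2])  # inconsistent never-with-birth
        assert pd.isna(got.iloc[3])  # consistent never: excluded, not coded
        assert pd.isna(got.iloc[4])

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            dichotomize(self._frame(height_cm=160.0), "tallness")

    @given(height=st.floats(min_value=100, max_value=200, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_strict_boundary_never_exposed_at_threshold(self, height):
        exposed = dichotomize(pd.DataFrame({"height_cm": [height]}), "short_stature").iloc[0]
        if height == 150.0:
            assert exposed == False  # noqa: E712
        else:
            assert exposed == (height < 150.0)


class TestCleanAgeFirstSex:
    def test_inconsistent_never_with_birth_is_missing(self):
        df = pd.DataFrame(
            {
                "age_first_sex_years": ["never", "never", 16, pd.NA, "inconsistent"],
                "age_first_birth_years": [19.0, np.nan, 20.0, np.nan, np.nan],
            }
        )
        out = clean_age_first_sex(df)
        assert pd.isna(out.iloc[0])          # never + a birth: inconsistent
        assert out.iloc[1] == "never"        # consistent never kept distinct
        assert out.iloc[2] == 16
        assert pd.isna(out.iloc[3])
        assert pd.isna(out.iloc[4])


class TestApplySurveyDefaults:
    def _records(self):
        return pd.DataFrame(
            {
                "survey_id": ["A", "A", "B"],
                "age_first_birth_years": [19.0, np.nan, 17.0],
                "gravid": pd.array([pd.NA, pd.NA, True], dtype="boolean"),
                "religion": ["muslim", "muslim", None],
            }
        )

    def test_nulligravid_assumption(self):
        out = apply_survey_defaults(self._records(), {"A": {"has_gravidity": False}})
        assert out["gravid"].iloc[0] == True  # parous => gravid  # noqa: E712
        assert out["gravid"].iloc[1] == False  # nulliparous => nulligravid  # noqa: E712
        assert out["gravid"].iloc[2] == True  # other survey untouched  # noqa: E712

    def test_religion_missing_indicator(self):
        out = apply_survey_defaults(self._records(), {"A": {"has_religion": False}})
        assert (out.loc[out["survey_id"] == "A", "religion"] == "missing").all()
        assert out.loc[out["survey_id"] == "B", "religion"].iloc[0] == "missing"

    def test_idempotent(self):
        meta = {"A": {"has_gravidity": False, "has_religion": False}}
        once = apply_survey_defaults(self._records(), meta)
        twice = apply_survey_defaults(once, meta)
        pd.testing.assert_frame_equal(once, twice)


class TestBuildAnalysisTable:
    def test_ipsv_restricted_to_ever_married(self, small_population):
        table = build_analysis_table(small_population, FACTORS["ipsv"])
        merged = table.join(small_population["ever_married"], rsuffix="_src")
        assert merged["ever_married"].all()

    def test_missing_exposure_rows_dropped(self, small_population):
        spec = FACTORS["short_stature"]
        table = build_analysis_table(small_population, spec)
        src = small_population.loc[table.index]
        assert src["height_cm"].notna().all()
        assert table.notna().all().all()

    def test_output_subset_of_eligible_input(self, small_population):
        for name in ("literacy", "fgm", "young_first_birth"):
            table = build_analysis_table(small_population, FACTORS[name])
            assert table.index.isin(small_population.index).all()
            assert len(table) <= len(small_population)

    def test_no_missing_all_rows_kept(self):
        n = 200
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "survey_id": rng.choice(["A", "B", "C"], n),
                "country": "X",
                "sampling_weight": 1.0,
                "age_years": rng.integers(15, 50, n),
                "fgm": rng.random(n) < 0.4,
                "literate": rng.random(n) < 0.5,
                "gravid": rng.random(n) < 0.6,
                "residence": rng.choice(["urban", "rural"], n),
                "religion": rng.choice(["christian", "muslim"], n),
                "vf_reported": rng.random(n) < 0.3,
                "ever_married": True,
            }
        )
        table = build_analysis_table(df, FACTORS["fgm"])
        assert len(table) == n

    def test_degenerate_exposure_raises(self):
        df = pd.DataFrame(
            {
                "survey_id": ["A"] * 10,
                "country": "X",
                "sampling_weight": 1.0,
                "age_years": 30,
                "fgm": [True] * 10,
                "literate": True,
                "gravid": True,
                "residence": "urban",
                "religion": "muslim",
                "vf_reported": False,
                "ever_married": True,
            }
        )
        with pytest.raises(ValueError, match="fgm"):
            build_analysis_table(df, FACTORS["fgm"])

    def test_age_groups_cover_survey_range(self):
        ages = pd.Series([15, 19, 20, 29, 30, 49])
        assert list(age_group(ages)) == ["15-19", "15-19", "20-29", "20-29", "30-49", "30-49"]


class TestExposureSpecGuards:
    def test_literacy_cannot_adjust_for_literacy(self):
        with pytest.raises(ValueError):
            ExposureSpec(name="x", coding_rule="literate", adjustment_set=("literate",))

    def test_first_birth_cannot_adjust_for_gravidity(self):
        with pytest.raises(ValueError):
            ExposureSpec(name="x", coding_rule="young_first_birth", adjustment_set=("gravid",))

    def test_registry_matches_design(self):
        assert FACTORS["ipsv"].match_ratio == 2
        assert FACTORS["young_first_sex"].match_ratio == 3
        assert FACTORS["short_stature"].match_ratio == 4
        assert FACTORS["young_first_birth"].match_ratio == 8
        assert FACTORS["ipsv"].weight_field == "dv_weight"
        assert not FACTORS["young_first_birth"].include_country_effects
        assert not FACTORS["permission"].include_country_effects
        for name in ("short_stature", "ipsv", "young_first_sex", "young_first_birth", "permission"):
            assert FACTORS[name].exact_on_survey
        for name in ("literacy", "post_primary", "fgm"):
            assert not FACTORS[name].exact_on_survey
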
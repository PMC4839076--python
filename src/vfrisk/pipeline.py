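"""End-to-end per-factor analysis: harmonize, match, fit, summarize."""

from __future__ import annotations

import pandas as pd

from .harmonize import FACTORS, apply_survey_defaults, build_analysis_table
from .matching import MatchSpec, match
from .model import McmcConfig, MisclassLogit
from .reporting import EffectEstimate, summarize_or

__all__ = ["run_factor"]


def run_factor(
    records: pd.DataFrame,
    factor: str,
    mcmc: McmcConfig | None = None,
    match_seed: int = 0,
    survey_meta: dict | None = None,
    priors=None,
    drop_covariates: tuple = (),
    effect_type: str = "direct",
) -> EffectEstimate:
    """Run the full pooled analysis for one risk factor.

    Harmonizes the woman-level records, builds the factor's complete-case
    analysis table, matches unexposed to exposed at the factor's ratio,
    fits the misclassification-adjusted model on the matched table, and
    returns the exposure odds ratio with its credible interval.
    """
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}; known: {sorted(FACTORS)}")
    spec = FACTORS[factor]
    if survey_meta:
        records = apply_survey_defaults(records, survey_meta)

    table = build_analysis_table(records, spec)
    result = match(
        table,
        MatchSpec(ratio=spec.match_ratio, exact_on_survey=spec.exact_on_survey, seed=match_seed),
    )
    matched = result.matched_frame

    adjustment = tuple(c for c in spec.adjustment_set if c not in drop_covariates)
    model = MisclassLogit.from_dataframe(
        matched,
        exposure="exposed",
        adjustment=adjustment,
        country_effects=spec.include_country_effects,
        priors=priors,
    )
    fitres = model.fit(mcmc if mcmc is not None else McmcConfig.test())
    n_exposed = int((matched["role"] == "exposed").sum())
    n_control = int((matched["role"] == "control").sum())
    return summarize_or(
        fitres,
        "exposed",
        factor=factor,
        effect_type=effect_type,
        n_exposed=n_exposed,
        n_control=n_control,
    )
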
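"""Odds-ratio summaries, direct-vs-total effects, and effect tables.

Posterior coefficient draws are summarized on the odds-ratio scale with
the posterior median as point estimate (safe under the monotone exp
transform) and equal-tailed 95% credible intervals. A factor is flagged
significant when its interval excludes 1. The percent change in odds,
``(1 - OR) * 100``, is carried alongside for prose reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EffectEstimate",
    "summarize_or",
    "crude_or_2x2",
    "effect_table",
    "direct_vs_total",
]


@dataclass
class EffectEstimate:
    """Odds ratio with 95% credible interval for one risk factor."""

    factor: str
    or_point: float
    cri_low: float
    cri_high: float
    effect_type: str = "direct"
    n_exposed: int = 0
    n_control: int = 0
    rhat_max: float = float("nan")

    def __post_init__(self):
        if not (self.cri_low <= self.or_point <= self.cri_high):
            raise ValueError("need cri_low <= or_point <= cri_high")
        if min(self.or_point, self.cri_low, self.cri_high) <= 0:
            raise ValueError("odds ratios must be positive")

    @property
    def significant(self) -> bool:
        """True iff the 95% CrI excludes an odds ratio of 1."""
        return self.cri_low > 1.0 or self.cri_high < 1.0

    @property
    def percent_change(self) -> float:
        """Percent change in the odds, (1 - OR) * 100 (positive = reduction)."""
        return (1.0 - self.or_point) * 100.0

    def __str__(self) -> str:
        return f"{self.factor}: OR {self.or_point:.2f} (95% CrI {self.cri_low:.2f}-{self.cri_high:.2f})"


def summarize_or(
    results,
    coefficient_name: str,
    factor: str | None = None,
    effect_type: str = "direct",
    n_exposed: int = 0,
    n_control: int = 0,
) -> EffectEstimate:
    """Summarize one coefficient's posterior as an odds ratio.

    Draws are exponentiated; the point estimate is the posterior median and
    the interval the equal-tailed 2.5th/97.5th percentiles. The maximum
    split R-hat over all model parameters is attached as a convergence
    check.
    """
    if coefficient_name not in results.draws:
        raise KeyError(
            f"no coefficient {coefficient_name!r}; available: {results.param_names}"
        )
    or_draws = np.exp(results.flat(coefficient_name))
    lo, hi = np.quantile(or_draws, [0.025, 0.975])
    return EffectEstimate(
        factor=factor or coefficient_name,
        or_point=float(np.median(or_draws)),
        cri_low=float(lo),
        cri_high=float(hi),
        effect_type=effect_type,
        n_exposed=n_exposed,
        n_control=n_control,
        rhat_max=results.max_rhat,
    )


def crude_or_2x2(a: int, b: int, c: int, d: int) -> float:
    """Crude odds ratio of a 2x2 table: (a*d)/(b*c).

    ``a``/``b`` are cases/non-cases among the exposed, ``c``/``d`` among
    the unexposed. Returns ``inf`` when ``b*c == 0`` with ``a*d > 0`` and
    ``nan`` (undefined) when a table row or column is empty. Symmetric
    under the simultaneous swap a<->d, b<->c.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("2x2 cells must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return math.nan
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def effect_table(estimates) -> pd.DataFrame:
    """Render effect estimates as a display table (ORs to two decimals).

    One row per factor with the formatted ``OR (low-high)`` string, a
    significance (bolding) flag, and a footnote marker for factors
    estimated in an eligibility-restricted population.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("effect_table needs at least one estimate")
    footnotes = {
        "ipsv": "among married and/or ever-married women",
        "young_first_sex": "among sexually active women",
        "young_first_birth": "among primi/multiparous women",
    }
    rows = []
    for est in estimates:
        rows.append(
            {
                "factor": est.factor,
                "effect_type": est.effect_type,
                "or_cri": f"{est.or_point:.2f} ({est.cri_low:.2f}-{est.cri_high:.2f})",
                "significant": est.significant,
                "percent_change": round(est.percent_change, 1),
                "n_exposed": est.n_exposed,
                "n_control": est.n_control,
                "rhat_max": est.rhat_max,
                "footnote": footnotes.get(est.factor, ""),
            }
        )
    return pd.DataFrame(rows)


#: factors whose default adjustment set contains gravidity as a plausible
#: mediator, so a total effect (gravidity omitted) is meaningful
MEDIATED_FACTORS = ("literacy", "post_primary")


def direct_vs_total(records: pd.DataFrame, factor: str, mcmc=None, match_seed: int = 0,
                    survey_meta: dict | None = None, priors=None):
    """Direct and total effect of a literacy/education factor.

    The direct effect adjusts for gravidity (a likely mediator between
    literacy/education and fistula); the total effect omits it. Both models
    are fitted on the same matched table. Only factors whose default
    adjustment set includes gravidity are accepted.
    """
    from .pipeline import run_factor

    if factor not in MEDIATED_FACTORS:
        raise ValueError(
            f"direct vs total effects are defined for {MEDIATED_FACTORS}, not {factor!r}"
        )
    direct = run_factor(
        records, factor, mcmc=mcmc, match_seed=match_seed,
        survey_meta=survey_meta, priors=priors, effect_type="direct",
    )
    total = run_factor(
        records, factor, mcmc=mcmc, match_seed=match_seed,
        survey_meta=survey_meta, priors=priors, drop_covariates=("gravid",),
        effect_type="total",
    )
    return direct, total
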
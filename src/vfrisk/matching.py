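"""k:1 nearest-neighbor matching of unexposed to exposed women.

Matching is the semi-parametric preprocessing step of the pooled analysis:
each exposed woman receives up to k unexposed controls that are nearest in
(sampling weight, age at interview), with the survey identifier either an
exact constraint or a strong same-survey preference. The subsequent
regression on the matched table is then doubly robust — consistent if
either the matching or the outcome model is right.

Algorithm: greedy sequential nearest-neighbor without replacement. Exposed
units are processed in seed-shuffled order; distances are Euclidean on
(weight, age) standardized against the pre-match table; candidate ties are
broken by row order. When the survey constraint is a preference rather
than exact, cross-survey distances carry a large additive penalty, so
same-survey controls are always preferred but an exposed woman in a survey
with no remaining controls can still be matched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MatchSpec", "MatchedSet", "MatchResult", "match", "balance_table"]

logger = logging.getLogger(__name__)

#: additive distance penalty for cross-survey candidates in preference mode;
#: far larger than any standardized within-survey distance can be.
CROSS_SURVEY_PENALTY = 1e6


@dataclass(frozen=True)
class MatchSpec:
    """Configuration of one matching run."""

    ratio: int = 1
    exact_on_survey: bool = False
    distance_variables: tuple[str, str] = ("weight", "age_years")
    with_replacement: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.ratio < 1:
            raise ValueError("ratio must be a positive integer")


@dataclass
class MatchedSet:
    """One exposed row and its matched controls (row labels of the input)."""

    exposed_row: object
    control_rows: list
    distances: list


@dataclass
class MatchResult:
    sets: list
    matched_frame: pd.DataFrame
    n_exposed_dropped: int

    def __iter__(self):
        return iter(self.sets)


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    if sd == 0:
        return np.zeros_like(values, dtype=float)
    return (values - values.mean()) / sd


def match(rows: pd.DataFrame, spec: MatchSpec) -> MatchResult:
    """Greedily match up to ``spec.ratio`` controls to every exposed row.

    ``rows`` must carry boolean ``exposed``, ``survey_id``, and the two
    distance variables. Returns the matched sets, plus a long-format frame
    of the retained rows with ``set_id`` and ``role`` columns; all unmatched
    rows are excluded. Exposed rows with zero eligible controls are dropped
    with a logged count (this happens under the exact constraint when a
    survey has exposed women but no controls left).
    """
    if rows.empty:
        raise ValueError("empty input table")
    exp_mask = rows["exposed"].astype(bool).to_numpy()
    if exp_mask.all() or not exp_mask.any():
        raise ValueError("need at least one exposed and one unexposed row")

    # standardization constants from the full pre-match table
    z = np.column_stack(
        [_standardize(rows[v].to_numpy(dtype=float)) for v in spec.distance_variables]
    )
    survey = rows["survey_id"].to_numpy()

    exp_idx = np.flatnonzero(exp_mask)
    ctl_idx = np.flatnonzero(~exp_mask)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(exp_idx.size)

    ctl_z = z[ctl_idx]
    ctl_survey = survey[ctl_idx]
    used = np.zeros(ctl_idx.size, dtype=bool)
    # per-survey candidate positions for fast same-survey lookup
    by_survey: dict = {}
    for pos, s in enumerate(ctl_survey):
        by_survey.setdefault(s, []).append(pos)
    by_survey = {s: np.asarray(p) for s, p in by_survey.items()}

    labels = rows.index.to_numpy()
    sets: list[MatchedSet] = []
    n_dropped = 0

    def _take_nearest(cand: np.ndarray, point: np.ndarray, k: int):
        if spec.with_replacement:
            avail = cand
        else:
            avail = cand[~used[cand]]
        if avail.size == 0:
            return [], []
        d = np.sqrt(((ctl_z[avail] - point) ** 2).sum(axis=1))
        # stable sort: ties broken by candidate row order
        sel = np.argsort(d, kind="stable")[:k]
        picked = avail[sel]
        if not spec.with_replacement:
            used[picked] = True
        return list(picked), list(d[sel])

    for oi in order:
        i = exp_idx[oi]
        point = z[i]
        k = spec.ratio
        if spec.exact_on_survey:
            cand = by_survey.get(survey[i], np.empty(0, dtype=int))
            picked, dists = _take_nearest(cand, point, k)
        else:
            cand = by_survey.get(survey[i], np.empty(0, dtype=int))
            picked, dists = _take_nearest(cand, point, k)
            if len(picked) < k:
                # same-survey pool exhausted: fall back to other surveys,
                # whose distances carry the cross-survey penalty
                other = np.flatnonzero(ctl_survey != survey[i])
                more, mored = _take_nearest(other, point, k - len(picked))
                picked += more
                dists += [d + CROSS_SURVEY_PENALTY for d in mored]
        if not picked:
            n_dropped += 1
            continue
        sets.append(
            MatchedSet(
                exposed_row=labels[i],
                control_rows=[labels[ctl_idx[p]] for p in picked],
                distances=dists,
            )
        )

    if n_dropped:
        logger.warning(
            "%d exposed rows dropped: no eligible controls%s",
            n_dropped,
            " under the exact survey constraint" if spec.exact_on_survey else "",
        )

    row_labels: list = []
    set_ids: list = []
    roles: list = []
    for sid, mset in enumerate(sets):
        row_labels.append(mset.exposed_row)
        set_ids.append(sid)
        roles.append("exposed")
        row_labels.extend(mset.control_rows)
        set_ids.extend([sid] * len(mset.control_rows))
        roles.extend(["control"] * len(mset.control_rows))
    if row_labels:
        matched = rows.loc[row_labels].assign(set_id=set_ids, role=roles)
    else:
        matched = rows.iloc[0:0].assign(set_id=[], role=[])
    return MatchResult(sets=sets, matched_frame=matched, n_exposed_dropped=n_dropped)


def _smd(mean_e, mean_c, pooled_sd):
    if pooled_sd == 0:
        return 0.0 if mean_e == mean_c else float("nan")
    return (mean_e - mean_c) / pooled_sd


def balance_table(before_rows: pd.DataFrame, result: MatchResult, variables=("weight", "age_years")) -> dict:
    """Covariate balance before and after matching.

    For each distance variable: exposed/control means and the standardized
    mean difference, where the standardizing pooled SD comes from the
    pre-match sample (so before/after SMDs share a scale). A zero pooled SD
    yields SMD 0 when means agree and NaN (flagged undefined) otherwise.
    """
    if before_rows.empty or not result.sets:
        raise ValueError("balance_table needs non-empty pre-match and matched data")
    matched = result.matched_frame
    report: dict = {}
    for v in variables:
        be = before_rows.loc[before_rows["exposed"].astype(bool), v].to_numpy(dtype=float)
        bc = before_rows.loc[~before_rows["exposed"].astype(bool), v].to_numpy(dtype=float)
        ae = matched.loc[matched["role"] == "exposed", v].to_numpy(dtype=float)
        ac = matched.loc[matched["role"] == "control", v].to_numpy(dtype=float)
        var_e = be.var(ddof=1) if be.size > 1 else 0.0
        var_c = bc.var(ddof=1) if bc.size > 1 else 0.0
        pooled_sd = float(np.sqrt((var_e + var_c) / 2.0))
        smd_before = _smd(be.mean(), bc.mean(), pooled_sd)
        smd_after = _smd(ae.mean(), ac.mean(), pooled_sd)
        report[v] = {
            "mean_exposed_before": float(be.mean()),
            "mean_control_before": float(bc.mean()),
            "mean_exposed_after": float(ae.mean()),
            "mean_control_after": float(ac.mean()),
            "pooled_sd": pooled_sd,
            "smd_before": float(smd_before),
            "smd_after": float(smd_after),
            "undefined": bool(np.isnan(smd_before) or np.isnan(smd_after)),
        }
    report["n_exposed_matched"] = len(result.sets)
    report["n_controls_matched"] = int(sum(len(s.control_rows) for s in result.sets))
    report["n_exposed_dropped"] = result.n_exposed_dropped
    return report
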
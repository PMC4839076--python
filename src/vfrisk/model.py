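"""Misclassification-adjusted Bayesian grouped logistic regression.

The self-reported outcome (lifetime vaginal fistula symptoms) is an
imperfect measurement of the latent true status. With common sensitivity
``Se`` and specificity ``Sp`` across surveys, the probability of a
*positive report* for covariate pattern ``i`` is

    p_i = pi_i * Se + (1 - pi_i) * (1 - Sp),
    logit(pi_i) = alpha + beta . x_i,

and, grouping women by covariate pattern, the reported-positive counts are
``y_i ~ Binomial(N_i, p_i)``. Priors: ``alpha, beta ~ Normal(0, sd 20)``
(effectively non-informative on the log-odds scale), and uniform priors on
``Se`` over (0.9510, 0.9990) and ``Sp`` over (0.9985, 0.9995) — the
credible ranges of a prior validation of fistula self-report against
pelvic examination. Because the outcome is rare, even the tiny
false-positive rate ``1 - Sp`` dilutes the case pool substantially, which
attenuates naive odds ratios toward 1; the latent-class likelihood undoes
that attenuation.

With ``Se = Sp = 1`` (degenerate bounds) the model reduces exactly to
standard grouped logistic regression, which provides the package's main
correctness oracle against maximum-likelihood fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

from . import sampler as _sampler

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "ParameterState",
    "apparent_prob",
    "group_patterns",
    "MisclassLogit",
    "MisclassLogitResults",
]

#: reference categories for dummy coding, fixed for reproducibility
REFERENCE_CATEGORIES = {
    "age_group": "30-49",
    "religion": "christian",
}

_EPS = 1e-300


@dataclass(frozen=True)
class PriorSpec:
    """Priors of the latent-class model.

    ``coef_sd`` is the standard deviation (not variance) of the zero-mean
    normal priors on the intercept and coefficients. ``se_bounds`` and
    ``sp_bounds`` are the supports of the uniform priors on sensitivity and
    specificity; degenerate bounds (lo == hi) fix the parameter, and
    ``(1, 1)`` for both recovers ordinary logistic regression.
    """

    coef_sd: float = 20.0
    se_bounds: tuple[float, float] = (0.9510, 0.9990)
    sp_bounds: tuple[float, float] = (0.9985, 0.9995)

    def __post_init__(self):
        if self.coef_sd <= 0:
            raise ValueError("coef_sd must be positive")
        for name, (lo, hi) in (("se_bounds", self.se_bounds), ("sp_bounds", self.sp_bounds)):
            if not (0.0 < lo <= hi <= 1.0):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi <= 1")

    @classmethod
    def perfect_test(cls, coef_sd: float = 20.0) -> "PriorSpec":
        """Priors of the naive model: Se and Sp fixed at 1."""
        return cls(coef_sd=coef_sd, se_bounds=(1.0, 1.0), sp_bounds=(1.0, 1.0))


@dataclass(frozen=True)
class McmcConfig:
    """Sampler run lengths. ``full`` is 3 chains x 30,000 retained
    draws after 2,500 warm-up; ``test`` is a short preset for simulation
    studies and the test suite."""

    chains: int = 3
    warmup: int = 2_500
    samples_per_chain: int = 30_000
    seed: int = 0

    def __post_init__(self):
        if min(self.chains, self.warmup, self.samples_per_chain) <= 0:
            raise ValueError("chains, warmup and samples_per_chain must be positive")

    @classmethod
    def full(cls, seed: int = 0) -> "McmcConfig":
        return cls(chains=3, warmup=2_500, samples_per_chain=30_000, seed=seed)

    @classmethod
    def test(cls, seed: int = 0) -> "McmcConfig":
        return cls(chains=3, warmup=1_000, samples_per_chain=1_000, seed=seed)


@dataclass
class ParameterState:
    """One point in parameter space: intercept, coefficient map, Se, Sp."""

    alpha: float
    beta: dict[str, float]
    se: float = 1.0
    sp: float = 1.0


def apparent_prob(pi, se, sp):
    """Probability of a positive *report* given true-status probability.

    ``p = pi*Se + (1-pi)*(1-Sp)``; always inside the envelope
    ``[1-Sp, Se]``, and increasing in ``pi`` whenever ``Se + Sp > 1``.
    """
    pi = np.asarray(pi, dtype=float)
    return pi * se + (1.0 - pi) * (1.0 - sp)


def group_patterns(rows: pd.DataFrame, design_columns, outcome: str = "outcome") -> pd.DataFrame:
    """Collapse woman-level rows into covariate-pattern groups.

    Returns one row per distinct pattern of ``design_columns`` with ``y``
    (reported-positive count) and ``n`` (pattern size). Grouping converts
    the Bernoulli likelihood into an equivalent binomial one, which makes
    MCMC cost independent of the number of women.
    """
    if rows.empty:
        raise ValueError("cannot group an empty table")
    design_columns = list(design_columns)
    missing = [c for c in design_columns + [outcome] if c not in rows.columns]
    if missing:
        raise ValueError(f"columns absent from table: {missing}")
    if rows[design_columns + [outcome]].isna().any().any():
        raise ValueError("rows must be complete on design columns and outcome")
    out = (
        rows.assign(_y=rows[outcome].astype(int))
        .groupby(design_columns, observed=True)
        .agg(y=("_y", "sum"), n=("_y", "size"))
        .reset_index()
    )
    return out


def _build_design(groups: pd.DataFrame, design_columns) -> tuple[np.ndarray, list[str]]:
    """Dummy-code pattern columns into a dense design matrix (no intercept
    column; the intercept is a separate parameter)."""
    mats = []
    names: list[str] = []
    for col in design_columns:
        vals = groups[col]
        if vals.dtype == bool or str(vals.dtype) == "boolean" or set(vals.unique()) <= {0, 1, True, False}:
            mats.append(vals.astype(float).to_numpy()[:, None])
            names.append(col)
            continue
        cats = sorted(map(str, vals.unique()))
        ref = REFERENCE_CATEGORIES.get(col)
        if ref is None or ref not in cats:
            ref = cats[0]
        for cat in cats:
            if cat == ref:
                continue
            mats.append((vals.astype(str) == cat).astype(float).to_numpy()[:, None])
            names.append(f"{col}[{cat}]")
    X = np.hstack(mats) if mats else np.empty((len(groups), 0))
    return X, names


class MisclassLogit:
    """Latent-class grouped-binomial logistic regression model.

    Parameters
    ----------
    y, n : array-like of int
        Reported-positive count and size of each covariate-pattern group.
    X : ndarray
        Design matrix (one row per group, no intercept column).
    exog_names : sequence of str
        Column names of ``X``.
    priors : PriorSpec
    """

    def __init__(self, y, n, X, exog_names, priors: PriorSpec | None = None):
        self.y = np.asarray(y, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size or self.n.size != self.y.size:
            raise ValueError("inconsistent shapes of y, n, X")
        if np.any(self.y < 0) or np.any(self.n <= 0) or np.any(self.y > self.n):
            raise ValueError("need 0 <= y <= n with n > 0 in every group")
        self.exog_names = list(exog_names)
        if len(self.exog_names) != self.X.shape[1]:
            raise ValueError("exog_names must match design-matrix columns")
        self.priors = priors if priors is not None else PriorSpec()
        self._check_rank()
        # binomial combinatorial constant, fixed given the data
        self._log_binom = (
            gammaln(self.n + 1) - gammaln(self.y + 1) - gammaln(self.n - self.y + 1)
        )
        self._se_free = self.priors.se_bounds[0] < self.priors.se_bounds[1]
        self._sp_free = self.priors.sp_bounds[0] < self.priors.sp_bounds[1]

    # ------------------------------------------------------------------ #
    # construction from data frames

    @classmethod
    def from_dataframe(
        cls,
        rows: pd.DataFrame,
        exposure: str = "exposed",
        adjustment=(),
        country_effects: bool = False,
        outcome: str = "outcome",
        priors: PriorSpec | None = None,
    ) -> "MisclassLogit":
        """Build the model from a woman-level (matched) analysis table.

        Groups rows by covariate pattern over the exposure, the adjustment
        covariates and (optionally) country dummies, then dummy-codes the
        patterns with the declared reference categories.
        """
        design_cols = [exposure] + [c for c in adjustment if c != exposure]
        if country_effects:
            design_cols.append("country")
        groups = group_patterns(rows, design_cols, outcome=outcome)
        X, names = _build_design(groups, design_cols)
        model = cls(groups["y"], groups["n"], X, names, priors=priors)
        model.groups = groups
        return model

    def _check_rank(self):
        d = self.X.shape[1]
        if d == 0:
            return
        Xi = np.hstack([np.ones((self.X.shape[0], 1)), self.X])
        rank = np.linalg.matrix_rank(Xi)
        if rank < Xi.shape[1]:
            # identify offending columns by greedy inclusion
            bad = []
            cols = [np.ones(self.X.shape[0])]
            for j in range(d):
                trial = np.column_stack(cols + [self.X[:, j]])
                if np.linalg.matrix_rank(trial) == trial.shape[1]:
                    cols.append(self.X[:, j])
                else:
                    bad.append(self.exog_names[j])
            raise ValueError(f"design matrix not full rank; collinear columns: {bad}")

    # ------------------------------------------------------------------ #
    # densities

    def _unpack(self, state: ParameterState):
        beta = np.array([state.beta.get(name, 0.0) for name in self.exog_names])
        return state.alpha, beta, state.se, state.sp

    def loglike(self, state: ParameterState) -> float:
        """Grouped binomial log-likelihood (combinatorial constant included)."""
        alpha, beta, se, sp = self._unpack(state)
        return float(self._loglike_vec(alpha, beta, se, sp))

    def _loglike_vec(self, alpha, beta, se, sp):
        pi = expit(alpha + self.X @ beta)
        p = np.clip(apparent_prob(pi, se, sp), 0.0, 1.0)
        # p = 0 with y > 0 (or p = 1 with y < n) has probability zero: -inf
        with np.errstate(divide="ignore", invalid="ignore"):
            t_pos = np.where(self.y > 0, self.y * np.log(p), 0.0)
            t_neg = np.where(self.n - self.y > 0, (self.n - self.y) * np.log1p(-p), 0.0)
        return float(np.sum(self._log_binom + t_pos + t_neg))

    def log_prior(self, state: ParameterState) -> float:
        """Normal(0, coef_sd) on alpha and every beta; uniform on Se, Sp
        within their bounds (-inf outside)."""
        alpha, beta, se, sp = self._unpack(state)
        sd = self.priors.coef_sd
        coefs = np.concatenate([[alpha], beta])
        lp = float(
            np.sum(-0.5 * np.log(2 * np.pi * sd**2) - 0.5 * (coefs / sd) ** 2)
        )
        for val, (lo, hi) in ((se, self.priors.se_bounds), (sp, self.priors.sp_bounds)):
            if lo < hi:
                if not (lo <= val <= hi):
                    return -np.inf
                lp += -np.log(hi - lo)
            elif val != lo:
                return -np.inf
        return lp

    def logpost(self, state: ParameterState) -> float:
        lp = self.log_prior(state)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.loglike(state)

    # ------------------------------------------------------------------ #
    # unconstrained parameterization: theta = [alpha, beta..., u_se?, u_sp?]
    # with se = lo + (hi-lo)*expit(u_se); the uniform prior plus Jacobian
    # gives log p(u) = log expit(u) + log expit(-u) up to a constant.

    @property
    def _dim(self) -> int:
        return 1 + self.X.shape[1] + int(self._se_free) + int(self._sp_free)

    def _theta_to_params(self, theta):
        d = self.X.shape[1]
        alpha = theta[0]
        beta = theta[1 : 1 + d]
        pos = 1 + d
        lo, hi = self.priors.se_bounds
        if self._se_free:
            se = lo + (hi - lo) * expit(theta[pos])
            pos += 1
        else:
            se = lo
        lo, hi = self.priors.sp_bounds
        sp = lo + (hi - lo) * expit(theta[pos]) if self._sp_free else lo
        return alpha, beta, se, sp

    def _logpost_grad(self, theta):
        """Log posterior density and gradient on the unconstrained scale."""
        d = self.X.shape[1]
        alpha, beta, se, sp = self._theta_to_params(theta)
        eta = alpha + self.X @ beta
        pi = expit(eta)
        p = np.clip(apparent_prob(pi, se, sp), _EPS, 1.0 - 1e-16)
        ll = self._log_binom + self.y * np.log(p) + (self.n - self.y) * np.log1p(-p)
        dll_dp = self.y / p - (self.n - self.y) / (1.0 - p)
        dp_deta = (se + sp - 1.0) * pi * (1.0 - pi)
        g_eta = dll_dp * dp_deta
        grad = np.empty_like(theta)
        grad[0] = g_eta.sum()
        grad[1 : 1 + d] = self.X.T @ g_eta

        sd = self.priors.coef_sd
        coefs = theta[: 1 + d]
        lp = ll.sum() - 0.5 * np.sum((coefs / sd) ** 2) - (1 + d) * 0.5 * np.log(2 * np.pi * sd**2)
        grad[: 1 + d] -= coefs / sd**2

        pos = 1 + d
        if self._se_free:
            u = theta[pos]
            s = expit(u)
            lo, hi = self.priors.se_bounds
            dse_du = (hi - lo) * s * (1 - s)
            # uniform prior cancels against the Jacobian's (hi-lo) factor
            lp += np.log(s) + np.log(1 - s)
            grad[pos] = float(np.sum(dll_dp * pi) * dse_du) + (1 - 2 * s)
            pos += 1
        if self._sp_free:
            u = theta[pos]
            s = expit(u)
            lo, hi = self.priors.sp_bounds
            dsp_du = (hi - lo) * s * (1 - s)
            lp += np.log(s) + np.log(1 - s)
            grad[pos] = float(np.sum(-dll_dp * (1.0 - pi)) * dsp_du) + (1 - 2 * s)
        return lp, grad

    def _logpost_theta(self, theta):
        return self._logpost_grad(theta)[0]

    # ------------------------------------------------------------------ #
    # fitting

    def fit_map(self):
        """Posterior mode (MAP) on the unconstrained scale via L-BFGS."""
        d = self.X.shape[1]
        theta0 = np.zeros(self._dim)
        rate = np.clip(self.y.sum() / self.n.sum(), 1e-6, 1 - 1e-6)
        theta0[0] = logit(rate)

        def nlp(t):
            lp, g = self._logpost_grad(t)
            return -lp, -g

        res = minimize(nlp, theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10})
        return res.x

    def fit(self, mcmc: McmcConfig | None = None) -> "MisclassLogitResults":
        """Sample the posterior; returns results with draws and diagnostics."""
        mcmc = mcmc if mcmc is not None else McmcConfig()
        theta_map = self.fit_map()

        draws_u, accept = _sampler.run_chains(
            self._logpost_theta,
            theta_map,
            chains=mcmc.chains,
            warmup=mcmc.warmup,
            samples_per_chain=mcmc.samples_per_chain,
            seed=mcmc.seed,
            grad=lambda t: self._logpost_grad(t)[1],
        )

        # transform draws to the natural scale
        names = ["alpha"] + self.exog_names
        d = self.X.shape[1]
        out = {}
        out["alpha"] = draws_u[:, :, 0]
        for j, name in enumerate(self.exog_names):
            out[name] = draws_u[:, :, 1 + j]
        pos = 1 + d
        lo, hi = self.priors.se_bounds
        if self._se_free:
            out["se"] = lo + (hi - lo) * expit(draws_u[:, :, pos])
            pos += 1
        else:
            out["se"] = np.full(draws_u.shape[:2], lo)
        lo, hi = self.priors.sp_bounds
        if self._sp_free:
            out["sp"] = lo + (hi - lo) * expit(draws_u[:, :, pos])
        else:
            out["sp"] = np.full(draws_u.shape[:2], lo)

        alpha_map, beta_map, se_map, sp_map = self._theta_to_params(theta_map)
        map_params = {"alpha": float(alpha_map), "se": float(se_map), "sp": float(sp_map)}
        map_params.update({n: float(b) for n, b in zip(self.exog_names, beta_map)})

        return MisclassLogitResults(
            model=self,
            draws=out,
            accept_rates=accept,
            map_params=map_params,
            mcmc=mcmc,
        )


class MisclassLogitResults:
    """Posterior draws plus diagnostics for a fitted model.

    ``draws`` maps parameter name to a (chains, draws) array. Point
    estimates are posterior medians; intervals are equal-tailed 95%
    credible intervals; R-hat is the split-chain potential scale reduction
    factor and ESS the bulk effective sample size.
    """

    def __init__(self, model, draws, accept_rates, map_params, mcmc):
        self.model = model
        self.draws = draws
        self.accept_rates = np.asarray(accept_rates)
        self.map_params = map_params
        self.mcmc = mcmc
        self.param_names = list(draws)

    def _get(self, name):
        if name not in self.draws:
            raise KeyError(
                f"no parameter {name!r}; available: {self.param_names}"
            )
        return self.draws[name]

    def flat(self, name) -> np.ndarray:
        """All retained draws of one parameter, chains concatenated."""
        return self._get(name).reshape(-1)

    def median(self, name) -> float:
        return float(np.median(self.flat(name)))

    def credible_interval(self, name, level: float = 0.95):
        q = (1 - level) / 2
        lo, hi = np.quantile(self.flat(name), [q, 1 - q])
        return float(lo), float(hi)

    def rhat(self, name) -> float:
        arr = self._get(name)
        if np.ptp(arr) == 0:  # fixed parameter (degenerate prior)
            return 1.0
        return _sampler.split_rhat(arr)

    def ess(self, name) -> float:
        arr = self._get(name)
        if np.ptp(arr) == 0:
            return float("nan")
        return _sampler.effective_sample_size(arr)

    @property
    def max_rhat(self) -> float:
        return max(self.rhat(n) for n in self.param_names)

    def or_estimate(self, name, **kwargs):
        """Odds-ratio summary of one coefficient (see reporting.summarize_or)."""
        from .reporting import summarize_or

        return summarize_or(self, name, **kwargs)

    def summary(self) -> pd.DataFrame:
        """Posterior summary table: median, 95% CrI, R-hat, ESS."""
        rows = []
        for name in self.param_names:
            lo, hi = self.credible_interval(name)
            rows.append(
                {
                    "parameter": name,
                    "median": self.median(name),
                    "cri_2.5%": lo,
                    "cri_97.5%": hi,
                    "rhat": self.rhat(name),
                    "ess": self.ess(name),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def to_npz(self, path) -> None:
        """Store draws as named (chains, draws) arrays."""
        np.savez_compressed(path, **{k: v for k, v in self.draws.items()})
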
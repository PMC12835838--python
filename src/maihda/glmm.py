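"""Random-intercept logistic regression by adaptive Gauss–Hermite quadrature.

The model: individual ``i`` in stratum ``s`` has outcome
``y_is ~ Bernoulli(logit^-1(x_is' beta + u_s))`` with ``u_s ~ N(0, sigma_u^2)``.
The marginal log-likelihood integrates the stratum effects out::

    l(beta, sigma_u^2) = sum_s log INT prod_i Bern(y_is | logit^-1(x_is'b + u))
                                     N(u; 0, sigma_u^2) du

Each one-dimensional integral is evaluated by Gauss–Hermite quadrature
recentred and rescaled at the stratum's posterior mode (adaptive quadrature),
which stays accurate even for large, unbalanced strata. Maximum-likelihood
estimates come from quasi-Newton optimization over ``(beta, log sigma_u)``;
standard errors from the numerically differentiated observed information.

Because every record in a stratum shares its covariates in the intersectional
design, rows are collapsed to per-(stratum, covariate-pattern) binomial counts
before any likelihood work; evaluation cost is then independent of cohort size.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import norm

from .cohort import Codebook, CohortTable

__all__ = [
    "FitOptions",
    "GlmmFit",
    "GlmmSpec",
    "GroupedBinomial",
    "RandomEffectPrediction",
    "fit_glmm",
    "marginal_loglik",
    "predict_random_effects",
    "wald_or_table",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class GlmmSpec:
    """Model specification: outcome, fixed-effect terms, grouping, coding.

    ``fixed_terms`` is the ordered list of categorical dimensions entering as
    main effects (empty tuple = intercept-only null model). ``coding`` maps
    each term to its non-reference categories in design order.
    """

    outcome: str
    positive: str
    fixed_terms: tuple[str, ...] = ()
    coding: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    references: Mapping[str, str] = field(default_factory=dict)
    group_col: str = "stratum_id"

    @classmethod
    def from_codebook(
        cls,
        codebook: Codebook,
        fixed_terms: Sequence[str] = (),
        references: Mapping[str, str] | None = None,
        group_col: str = "stratum_id",
    ) -> "GlmmSpec":
        refs: dict[str, str] = {}
        coding: dict[str, tuple[str, ...]] = {}
        for name in fixed_terms:
            var = codebook.variable(name)
            cats = var.analytic_categories
            ref = (references or {}).get(name, cats[0])
            if ref not in cats:
                raise ValueError(f"reference {ref!r} not an analytic category of {name!r}")
            refs[name] = ref
            coding[name] = tuple(c for c in cats if c != ref)
        return cls(
            outcome=codebook.outcome.name,
            positive=codebook.outcome_positive,
            fixed_terms=tuple(fixed_terms),
            coding=coding,
            references=refs,
            group_col=group_col,
        )

    @property
    def term_names(self) -> list[str]:
        names = ["Intercept"]
        for t in self.fixed_terms:
            names.extend(f"{t}[{c}]" for c in self.coding[t])
        return names

    def design(self, df: pd.DataFrame) -> np.ndarray:
        """Treatment-coded design matrix with leading intercept column."""
        cols = [np.ones(len(df))]
        for t in self.fixed_terms:
            for c in self.coding[t]:
                cols.append((df[t] == c).to_numpy(dtype=float))
        return np.column_stack(cols)


@dataclass
class GroupedBinomial:
    """Rows collapsed to binomial counts per (group, covariate pattern)."""

    X: np.ndarray          # (J, p) unique covariate patterns
    trials: np.ndarray     # (J,) record counts
    successes: np.ndarray  # (J,) positive-outcome counts
    group_idx: np.ndarray  # (J,) index into group_ids, non-decreasing
    group_ids: list[str]

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)

    @property
    def n_obs(self) -> int:
        return int(self.trials.sum())

    @classmethod
    def from_cohort(cls, cohort: CohortTable, spec: GlmmSpec) -> "GroupedBinomial":
        df = cohort.df
        if spec.group_col not in df.columns:
            raise ValueError(f"cohort lacks grouping column {spec.group_col!r}")
        y = (df[spec.outcome] == spec.positive).to_numpy(dtype=float)
        X = spec.design(df)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite design values")
        group_ids = np.unique(df[spec.group_col].to_numpy())
        gcode = np.searchsorted(group_ids, df[spec.group_col].to_numpy())
        key = np.column_stack([gcode.astype(float), X])
        uniq, inv = np.unique(key, axis=0, return_inverse=True)
        trials = np.bincount(inv).astype(float)
        successes = np.bincount(inv, weights=y)
        return cls(
            X=uniq[:, 1:],
            trials=trials,
            successes=successes,
            group_idx=uniq[:, 0].astype(int),
            group_ids=[str(g) for g in group_ids],
        )


def _bernoulli_loglik_terms(eta: np.ndarray, y: np.ndarray, n: np.ndarray) -> np.ndarray:
    # sum of individual Bernoulli log-densities for a collapsed pattern
    return y * log_expit(eta) + (n - y) * log_expit(-eta)


def _posterior_modes(
    eta: np.ndarray,
    grouped: GroupedBinomial,
    sigma_u2: float,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group mode and curvature scale of ``u -> loglik + log prior``.

    The objective is strictly concave (logistic log-likelihood plus Gaussian
    prior), so damped Newton converges from zero.
    """
    G = grouped.n_groups
    gidx, n, y = grouped.group_idx, grouped.trials, grouped.successes
    u = np.zeros(G)
    for _ in range(max_iter):
        p = expit(eta + u[gidx])
        grad = np.bincount(gidx, weights=y - n * p, minlength=G) - u / sigma_u2
        hess = -np.bincount(gidx, weights=n * p * (1 - p), minlength=G) - 1.0 / sigma_u2
        step = grad / hess
        np.clip(step, -5.0, 5.0, out=step)
        u -= step
        if np.max(np.abs(step)) < tol:
            break
    p = expit(eta + u[gidx])
    hess = -np.bincount(gidx, weights=n * p * (1 - p), minlength=G) - 1.0 / sigma_u2
    tau = np.sqrt(-1.0 / hess)
    return u, tau


_SIGMA_FLOOR = 1e-10


def marginal_loglik(
    beta: np.ndarray,
    sigma_u2: float,
    grouped: GroupedBinomial,
    nodes: int = 15,
) -> float:
    """Marginal log-likelihood via adaptive Gauss–Hermite quadrature.

    At ``sigma_u2 = 0`` the integral collapses and the value equals the
    ordinary logistic-regression log-likelihood.
    """
    if sigma_u2 < 0:
        raise ValueError("sigma_u2 must be non-negative")
    beta = np.asarray(beta, dtype=float)
    eta = grouped.X @ beta
    if sigma_u2 < _SIGMA_FLOOR:
        return float(
            _bernoulli_loglik_terms(eta, grouped.successes, grouped.trials).sum()
        )
    u_hat, tau = _posterior_modes(eta, grouped, sigma_u2)
    t, w = hermgauss(nodes)
    # integration points per group: u = u_hat + sqrt(2) tau t_q
    z = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * t[None, :]
    eta_q = eta[:, None] + z[grouped.group_idx]
    terms = _bernoulli_loglik_terms(
        eta_q, grouped.successes[:, None], grouped.trials[:, None]
    )
    G = grouped.n_groups
    per_group = np.zeros((G, nodes))
    np.add.at(per_group, grouped.group_idx, terms)
    log_prior = -0.5 * z**2 / sigma_u2 - 0.5 * np.log(2 * np.pi * sigma_u2)
    log_integrand = per_group + log_prior + t[None, :] ** 2 + np.log(w)[None, :]
    per_group_ll = logsumexp(log_integrand, axis=1) + 0.5 * np.log(2.0) + np.log(tau)
    return float(per_group_ll.sum())


@dataclass
class FitOptions:
    quad_nodes: int = 15
    max_iter: int = 500
    ftol: float = 1e-12
    gtol: float = 1e-6
    log_sd_bounds: tuple[float, float] = (-7.0, 3.0)
    #: fix the random-effect variance instead of estimating it (0.0 gives the
    #: ordinary logistic model); None = estimate.
    fix_sigma_u2: float | None = None


@dataclass
class GlmmFit:
    """Maximum-likelihood fit of the random-intercept logistic model."""

    spec: GlmmSpec
    term_names: list[str]
    beta: np.ndarray
    se_beta: np.ndarray
    cov_beta: np.ndarray
    sigma_u2: float
    loglik: float
    converged: bool
    at_boundary: bool
    separation_suspected: bool
    n_obs: int
    n_groups: int
    quad_nodes: int
    n_iter: int
    message: str
    objective_trace: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "terms": self.term_names,
            "beta": [float(b) for b in self.beta],
            "se_beta": [float(s) for s in self.se_beta],
            "sigma_u2": float(self.sigma_u2),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "at_boundary": bool(self.at_boundary),
            "separation_suspected": bool(self.separation_suspected),
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "quad_nodes": self.quad_nodes,
            "n_iter": self.n_iter,
            "message": self.message,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    p = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            xi, xj = h[i], h[j]
            if i == j:
                f0 = f(x)
                xp = x.copy(); xp[i] += xi
                xm = x.copy(); xm[i] -= xi
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / xi**2
            else:
                xpp = x.copy(); xpp[i] += xi; xpp[j] += xj
                xpm = x.copy(); xpm[i] += xi; xpm[j] -= xj
                xmp = x.copy(); xmp[i] -= xi; xmp[j] += xj
                xmm = x.copy(); xmm[i] -= xi; xmm[j] -= xj
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * xi * xj)
    return H


def fit_glmm(
    spec: GlmmSpec,
    cohort: CohortTable,
    options: FitOptions | None = None,
) -> GlmmFit:
    """Fit the model by ML over ``(beta, log sigma_u)``.

    The variance is parameterized as ``log sigma_u`` with a finite lower bound;
    an estimate pinned at that bound is reported as ``at_boundary`` with
    ``sigma_u2`` effectively zero. Non-convergence is flagged, never silent.
    """
    opts = options or FitOptions()
    grouped = GroupedBinomial.from_cohort(cohort, spec)
    if grouped.n_groups < 2 and opts.fix_sigma_u2 is None:
        raise ValueError("grouping variance unidentifiable with a single stratum")
    ybar = grouped.successes.sum() / grouped.trials.sum()
    if ybar in (0.0, 1.0):
        raise ValueError("outcome has no variation; model unidentifiable")

    p = grouped.X.shape[1]
    beta0 = np.zeros(p)
    beta0[0] = np.log(ybar / (1 - ybar))

    trace: list[float] = []
    fixed_s2 = opts.fix_sigma_u2

    if fixed_s2 is not None:
        def nll(theta: np.ndarray) -> float:
            return -marginal_loglik(theta, fixed_s2, grouped, opts.quad_nodes)

        x0 = beta0
        bounds = [(-30.0, 30.0)] * p
    else:
        def nll(theta: np.ndarray) -> float:
            s2 = float(np.exp(2.0 * theta[-1]))
            return -marginal_loglik(theta[:-1], s2, grouped, opts.quad_nodes)

        x0 = np.append(beta0, np.log(0.5))
        bounds = [(-30.0, 30.0)] * p + [opts.log_sd_bounds]

    res = minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        callback=lambda xk: trace.append(nll(xk)),
        options={"maxiter": opts.max_iter, "ftol": opts.ftol, "gtol": opts.gtol},
    )

    if fixed_s2 is not None:
        beta = res.x
        sigma_u2 = float(fixed_s2)
        at_boundary = False
    else:
        beta = res.x[:-1]
        sigma_u2 = float(np.exp(2.0 * res.x[-1]))
        at_boundary = bool(res.x[-1] <= opts.log_sd_bounds[0] + 1e-6)
        if at_boundary:
            sigma_u2 = 0.0

    separation = bool(np.max(np.abs(beta)) > 10.0)
    if separation:
        warnings.warn(
            "very large coefficient magnitude; possible complete separation "
            "(standard errors may be inflated)",
            RuntimeWarning,
        )

    # Observed information: numeric Hessian of the negative log-likelihood.
    # With the variance at its boundary (or fixed) only beta is profiled.
    se = np.full(p, np.nan)
    cov_beta = np.full((p, p), np.nan)
    try:
        if fixed_s2 is not None or at_boundary:
            s2_here = sigma_u2
            H = _numeric_hessian(
                lambda b: -marginal_loglik(b, s2_here, grouped, opts.quad_nodes), beta
            )
            cov = np.linalg.inv(H)
            cov_beta = cov
        else:
            H = _numeric_hessian(nll, res.x)
            cov = np.linalg.inv(H)
            cov_beta = cov[:p, :p]
        d = np.diag(cov_beta)
        se = np.where(d > 0, np.sqrt(np.maximum(d, 0)), np.nan)
    except np.linalg.LinAlgError:
        pass

    return GlmmFit(
        spec=spec,
        term_names=spec.term_names,
        beta=beta,
        se_beta=se,
        cov_beta=cov_beta,
        sigma_u2=sigma_u2,
        loglik=float(-res.fun),
        converged=bool(res.success),
        at_boundary=at_boundary,
        separation_suspected=separation,
        n_obs=grouped.n_obs,
        n_groups=grouped.n_groups,
        quad_nodes=opts.quad_nodes,
        n_iter=int(res.nit),
        message=str(res.message),
        objective_trace=trace,
    )


@dataclass
class RandomEffectPrediction:
    """Empirical-Bayes stratum effect: posterior mode and curvature spread."""

    stratum_id: str
    eb_value: float       # posterior mode of the stratum deviation, log-odds
    posterior_sd: float
    data_informed: bool   # False for strata with no records (prior-only)


def predict_random_effects(
    fit: GlmmFit,
    cohort: CohortTable,
    all_stratum_ids: Sequence[str] | None = None,
) -> list[RandomEffectPrediction]:
    """Posterior modes of the stratum deviations at the fitted parameters.

    Strata in ``all_stratum_ids`` absent from the cohort get the prior-only
    prediction (mode 0, sd ``sigma_u``). Shrinkage is automatic: the mode sits
    between 0 and the raw stratum residual, more so for smaller strata.
    """
    grouped = GroupedBinomial.from_cohort(cohort, fit.spec)
    eta = grouped.X @ fit.beta
    if fit.sigma_u2 < _SIGMA_FLOOR:
        u = np.zeros(grouped.n_groups)
        tau = np.zeros(grouped.n_groups)
    else:
        u, tau = _posterior_modes(eta, grouped, fit.sigma_u2)
    preds = {
        gid: RandomEffectPrediction(gid, float(ui), float(ti), True)
        for gid, ui, ti in zip(grouped.group_ids, u, tau)
    }
    out = list(preds.values())
    if all_stratum_ids is not None:
        prior_sd = float(np.sqrt(fit.sigma_u2))
        out = [
            preds.get(sid, RandomEffectPrediction(sid, 0.0, prior_sd, False))
            for sid in all_stratum_ids
        ]
    return out


def wald_or_table(fit: GlmmFit, level: float = 0.95) -> pd.DataFrame:
    """Odds ratios with Wald intervals: ``exp(beta -/+ z se)``."""
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    z = norm.ppf(0.5 + level / 2.0)
    rows = []
    for name, b, s in zip(fit.term_names, fit.beta, fit.se_beta):
        if np.isfinite(s):
            lo, hi = np.exp(b - z * s), np.exp(b + z * s)
        else:
            lo = hi = np.nan
        rows.append({"term": name, "OR": np.exp(b), "lower": lo, "upper": hi})
    return pd.DataFrame(rows, columns=["term", "OR", "lower", "upper"])
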
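"""The two-model MAIHDA workflow and its derived statistics.

Model 1 (null) is an intercept-only random-intercept logistic model over the
intersectional strata; model 2 (full) adds additive main effects for every
dimension while keeping the stratum random intercept. From the pair:

* **VPC** — share of latent-scale variance between strata,
  ``sigma_u^2 / (sigma_u^2 + pi^2/3)`` with the logistic residual fixed at 3.29;
* **PCV** — proportional drop in between-stratum variance from model 1 to
  model 2; its complement indexes residual intersectional interaction;
* **AUC** — discriminatory accuracy of stratum-based predicted probabilities,
  computed as the tie-corrected Mann–Whitney probability;
* per-stratum predicted probabilities decomposed into an additive part (fixed
  effects alone) and an interaction part (total minus additive), plus the
  null-model probabilities used for ranking and caterpillar displays.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.special import expit

from .cohort import Codebook, CohortTable
from .defaults import DEFAULT_REFERENCES
from .glmm import (
    FitOptions,
    GlmmFit,
    GlmmSpec,
    fit_glmm,
    predict_random_effects,
    wald_or_table,
)
from .strata import StrataSchema, Stratum, assign_strata

__all__ = [
    "LATENT_RESIDUAL_VARIANCE",
    "MaihdaOptions",
    "MaihdaResult",
    "StratumPrediction",
    "auc_discrimination",
    "auc_from_scores",
    "decompose_probability",
    "extremes",
    "pcv",
    "prediction_cis",
    "run_maihda",
    "stratum_predictions",
    "vpc",
]

#: Fixed level-1 residual variance of the latent-response formulation of the
#: logistic model (pi^2/3, conventionally rounded to 3.29).
LATENT_RESIDUAL_VARIANCE = 3.29


def vpc(sigma_u2: float) -> float:
    """Variance partition coefficient, percent, on the latent scale."""
    if sigma_u2 < 0:
        raise ValueError("sigma_u2 must be non-negative")
    return 100.0 * sigma_u2 / (sigma_u2 + LATENT_RESIDUAL_VARIANCE)


def pcv(sigma_null: float, sigma_full: float) -> float:
    """Proportional change in between-stratum variance, percent."""
    if sigma_null <= 0:
        raise ValueError("PCV undefined: null-model variance must be positive")
    if sigma_full < 0:
        raise ValueError("sigma_full must be non-negative")
    return 100.0 * (sigma_null - sigma_full) / sigma_null


def auc_from_scores(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney AUC with midrank tie correction (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: outcome is constant")
    r = rankdata(scores)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _individual_scores(fit: GlmmFit, cohort: CohortTable) -> tuple[np.ndarray, np.ndarray]:
    df = cohort.df
    eta = fit.spec.design(df) @ fit.beta
    preds = {p.stratum_id: p.eb_value for p in predict_random_effects(fit, cohort)}
    u = df[fit.spec.group_col].map(preds).to_numpy(dtype=float)
    y = (df[fit.spec.outcome] == fit.spec.positive).to_numpy(dtype=int)
    return expit(eta + u), y


def auc_discrimination(fit: GlmmFit, cohort: CohortTable, mode: str = "null") -> float:
    """Discriminatory accuracy of stratum predicted probabilities.

    Each individual is scored with their stratum's predicted probability
    (intercept or fixed effects plus the empirical-Bayes deviation, depending
    on which fit is passed); ``mode`` labels the model for sanity checking.
    """
    if mode not in ("null", "full"):
        raise ValueError("mode must be 'null' or 'full'")
    if mode == "null" and fit.spec.fixed_terms:
        raise ValueError("null mode expects an intercept-only fit")
    scores, y = _individual_scores(fit, cohort)
    return auc_from_scores(scores, y)


def decompose_probability(eta: float, eb: float) -> tuple[float, float, float]:
    """Split a stratum's predicted probability into additive and interaction
    parts, percent scale: ``(p_total, p_additive, p_total - p_additive)``.

    ``eta`` is the fixed-effect linear predictor, ``eb`` the empirical-Bayes
    stratum deviation, both log-odds.
    """
    p_total = 100.0 * float(expit(eta + eb))
    p_add = 100.0 * float(expit(eta))
    return p_total, p_add, p_total - p_add


@dataclass
class StratumPrediction:
    """Predicted probabilities for one stratum, percent scale.

    ``p_total`` combines the full model's fixed effects with the stratum's
    empirical-Bayes deviation; ``p_additive`` uses fixed effects alone;
    ``interaction`` is exactly their difference (percentage points). ``p_null``
    is the null-model probability used for ranking and caterpillar output.
    """

    stratum_id: str
    categories: tuple[str, ...]
    n_obs: int
    observed: bool
    p_total: float
    p_additive: float
    interaction: float
    p_null: float
    rank: int | None = None            # ascending rank by p_total, observed only
    ci_lower: float | None = None      # CI for p_total
    ci_upper: float | None = None
    null_ci_lower: float | None = None  # CI for p_null
    null_ci_upper: float | None = None
    # internals for CI simulation
    _x_row: np.ndarray | None = field(default=None, repr=False)
    _eb_full: float = field(default=0.0, repr=False)
    _sd_full: float = field(default=0.0, repr=False)
    _eb_null: float = field(default=0.0, repr=False)
    _sd_null: float = field(default=0.0, repr=False)


def stratum_predictions(
    null_fit: GlmmFit,
    full_fit: GlmmFit,
    schema: StrataSchema,
    cohort: CohortTable,
) -> list[StratumPrediction]:
    """Per-cell predictions over the whole cross-classification.

    Unobserved cells are additive-only (prior-mode deviation 0) and flagged.
    """
    cells = list(schema.all_cells())
    ids = [sid for sid, _ in cells]
    cell_df = pd.DataFrame([dict(zip(schema.names, cats)) for _, cats in cells])
    X_full = full_fit.spec.design(cell_df)
    eta_full = X_full @ full_fit.beta
    eta_null = np.full(len(cells), float(null_fit.beta[0]))

    eb_full = predict_random_effects(full_fit, cohort, all_stratum_ids=ids)
    eb_null = predict_random_effects(null_fit, cohort, all_stratum_ids=ids)
    counts = cohort.df["stratum_id"].value_counts()

    out = []
    for i, (sid, cats) in enumerate(cells):
        p_total, p_add, interaction = decompose_probability(
            float(eta_full[i]), eb_full[i].eb_value
        )
        p_null_ = 100.0 * float(expit(eta_null[i] + eb_null[i].eb_value))
        out.append(
            StratumPrediction(
                stratum_id=sid,
                categories=cats,
                n_obs=int(counts.get(sid, 0)),
                observed=eb_full[i].data_informed,
                p_total=p_total,
                p_additive=p_add,
                interaction=interaction,
                p_null=p_null_,
                _x_row=X_full[i],
                _eb_full=eb_full[i].eb_value,
                _sd_full=eb_full[i].posterior_sd,
                _eb_null=eb_null[i].eb_value,
                _sd_null=eb_null[i].posterior_sd,
            )
        )
    observed = sorted(
        (p for p in out if p.observed), key=lambda p: (p.p_total, p.stratum_id)
    )
    for r, p in enumerate(observed, start=1):
        p.rank = r
    return out


def _beta_draws(fit: GlmmFit, B: int, rng: np.random.Generator) -> np.ndarray:
    cov = np.asarray(fit.cov_beta, dtype=float)
    p = len(fit.beta)
    if not np.all(np.isfinite(cov)):
        return np.tile(fit.beta, (B, 1))
    # symmetrize and clip tiny negative eigenvalues before factorization
    cov = (cov + cov.T) / 2.0
    vals, vecs = np.linalg.eigh(cov)
    L = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return fit.beta + rng.standard_normal((B, p)) @ L.T


def prediction_cis(
    predictions: Sequence[StratumPrediction],
    null_fit: GlmmFit,
    full_fit: GlmmFit,
    B: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> list[StratumPrediction]:
    """Percentile intervals by parametric simulation, in place.

    Fixed effects are drawn from their asymptotic normal, the stratum
    deviation from its empirical-Bayes normal approximation (the prior for
    unobserved cells), ``B`` times; the interval is the percentile band.
    """
    if B < 100:
        warnings.warn("B < 100 replicates gives unstable percentile CIs", UserWarning)
    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    qs = [100.0 * alpha, 100.0 * (1.0 - alpha)]
    bf = _beta_draws(full_fit, B, rng)    # (B, p)
    bn = _beta_draws(null_fit, B, rng)    # (B, 1)
    z = rng.standard_normal((len(predictions), B))
    zn = rng.standard_normal((len(predictions), B))
    for i, pr in enumerate(predictions):
        eta = bf @ pr._x_row + pr._eb_full + pr._sd_full * z[i]
        p_draw = 100.0 * expit(eta)
        lo, hi = np.percentile(p_draw, qs)
        pr.ci_lower = min(float(lo), pr.p_total)
        pr.ci_upper = max(float(hi), pr.p_total)
        eta0 = bn[:, 0] + pr._eb_null + pr._sd_null * zn[i]
        p0 = 100.0 * expit(eta0)
        lo0, hi0 = np.percentile(p0, qs)
        pr.null_ci_lower = min(float(lo0), pr.p_null)
        pr.null_ci_upper = max(float(hi0), pr.p_null)
    return list(predictions)


def extremes(
    predictions: Sequence[StratumPrediction],
    k: int = 5,
    by: str = "p_null",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lowest-k and highest-k observed strata by the ranking probability.

    Rankings conventionally use the null-model probability (``by="p_null"``),
    which captures additive and interactive structure together; ties break by
    stratum ID. Both tables are sorted ascending.
    """
    if by not in ("p_null", "p_total"):
        raise ValueError("by must be 'p_null' or 'p_total'")
    obs = [p for p in predictions if p.observed]
    if len(obs) < 2 * k:
        warnings.warn(
            f"only {len(obs)} observed strata for 2k={2 * k}; tables truncated",
            UserWarning,
        )
    ranked = sorted(obs, key=lambda p: (getattr(p, by), p.stratum_id))

    def frame(chunk: list[StratumPrediction]) -> pd.DataFrame:
        rows = []
        for p in chunk:
            row = {"stratum_id": p.stratum_id}
            row.update({f"dim{i + 1}": c for i, c in enumerate(p.categories)})
            row.update(
                {
                    "n_obs": p.n_obs,
                    "probability": getattr(p, by),
                    "ci_lower": p.null_ci_lower if by == "p_null" else p.ci_lower,
                    "ci_upper": p.null_ci_upper if by == "p_null" else p.ci_upper,
                }
            )
            rows.append(row)
        return pd.DataFrame(rows)

    return frame(ranked[:k]), frame(ranked[-k:])


@dataclass
class MaihdaOptions:
    quad_nodes: int = 15
    ci_reps: int = 1000
    seed: int | None = None
    level: float = 0.95
    k_extremes: int = 5
    references: dict[str, str] | None = None


@dataclass
class MaihdaResult:
    """Paired null/full fits plus every derived MAIHDA statistic."""

    null_fit: GlmmFit
    full_fit: GlmmFit
    strata: list[Stratum]
    vpc_null: float
    vpc_full: float
    pcv: float
    interaction_share: float  # 100 - pcv: residual intersectional interaction
    auc_null: float
    auc_full: float
    predictions: list[StratumPrediction]
    n_observed_strata: int

    def summary(self) -> dict:
        return {
            "n_obs": self.null_fit.n_obs,
            "n_observed_strata": self.n_observed_strata,
            "n_possible_strata": len(self.predictions),
            "sigma_u2_null": float(self.null_fit.sigma_u2),
            "sigma_u2_full": float(self.full_fit.sigma_u2),
            "vpc_null": self.vpc_null,
            "vpc_full": self.vpc_full,
            "pcv": self.pcv,
            "interaction_share": self.interaction_share,
            "auc_null": self.auc_null,
            "auc_full": self.auc_full,
            "loglik_null": float(self.null_fit.loglik),
            "loglik_full": float(self.full_fit.loglik),
        }

    def summary_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.summary(), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def coefficients_table(self, level: float = 0.95) -> pd.DataFrame:
        return wald_or_table(self.full_fit, level)

    def stratum_table(self) -> pd.DataFrame:
        rows = []
        for p in self.predictions:
            row = {"stratum_id": p.stratum_id}
            row.update({f"dim{i + 1}": c for i, c in enumerate(p.categories)})
            row.update(
                {
                    "n_obs": p.n_obs,
                    "observed": p.observed,
                    "p_null": p.p_null,
                    "null_ci_lower": p.null_ci_lower,
                    "null_ci_upper": p.null_ci_upper,
                    "p_total": p.p_total,
                    "ci_lower": p.ci_lower,
                    "ci_upper": p.ci_upper,
                    "p_additive": p.p_additive,
                    "interaction": p.interaction,
                    "rank": p.rank,
                }
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def ranked_table(self) -> pd.DataFrame:
        """Observed strata sorted ascending by null-model probability
        (caterpillar-plot export)."""
        df = self.stratum_table()
        df = df[df["observed"]].sort_values(["p_null", "stratum_id"])
        return df.reset_index(drop=True)


def run_maihda(
    cohort: CohortTable,
    schema: StrataSchema,
    codebook: Codebook,
    options: MaihdaOptions | None = None,
) -> MaihdaResult:
    """Run the two-model workflow on a filtered cohort.

    The cohort is stratified if it lacks a ``stratum_id`` column. Fit failures
    propagate with the model identity attached.
    """
    opts = options or MaihdaOptions()
    if "stratum_id" not in cohort.df.columns:
        cohort, strata = assign_strata(cohort, schema)
    else:
        counts = cohort.df["stratum_id"].value_counts()
        strata = [
            Stratum(sid, cats, int(counts.get(sid, 0))) for sid, cats in schema.all_cells()
        ]
    if sum(1 for s in strata if s.observed) < 2:
        raise ValueError("need at least 2 observed strata")

    fit_opts = FitOptions(quad_nodes=opts.quad_nodes)
    if opts.references is not None:
        refs = dict(opts.references)
    else:
        refs = {n: r for n, r in DEFAULT_REFERENCES.items() if n in schema.names}
    null_spec = GlmmSpec.from_codebook(codebook, fixed_terms=())
    full_spec = GlmmSpec.from_codebook(codebook, fixed_terms=schema.names, references=refs)
    try:
        null_fit = fit_glmm(null_spec, cohort, fit_opts)
    except Exception as e:
        raise RuntimeError(f"null model (model 1) failed: {e}") from e
    try:
        full_fit = fit_glmm(full_spec, cohort, fit_opts)
    except Exception as e:
        raise RuntimeError(f"full model (model 2) failed: {e}") from e

    preds = stratum_predictions(null_fit, full_fit, schema, cohort)
    if opts.ci_reps:
        prediction_cis(
            preds, null_fit, full_fit, B=opts.ci_reps, seed=opts.seed, level=opts.level
        )
    pcv_val = pcv(null_fit.sigma_u2, full_fit.sigma_u2) if null_fit.sigma_u2 > 0 else float("nan")
    return MaihdaResult(
        null_fit=null_fit,
        full_fit=full_fit,
        strata=strata,
        vpc_null=vpc(null_fit.sigma_u2),
        vpc_full=vpc(full_fit.sigma_u2),
        pcv=pcv_val,
        interaction_share=100.0 - pcv_val,
        auc_null=auc_discrimination(null_fit, cohort, "null"),
        auc_full=auc_discrimination(full_fit, cohort, "full"),
        predictions=preds,
        n_observed_strata=sum(1 for s in strata if s.observed),
    )
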
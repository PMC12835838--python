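"""Random-intercept logistic model: likelihood oracles, fitting, EB prediction.

Independent oracles: dense trapezoid integration of the marginal likelihood,
statsmodels' ordinary logistic regression for the zero-variance limit, a grid
search for posterior modes, and R's lme4::glmer (matched quadrature order) for
a full small-sample fit.
"""

import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

import maihda as m
from maihda.glmm import GroupedBinomial, _posterior_modes

from conftest import toy_grouped_cohort

TOY_SPEC = m.GlmmSpec(outcome="online_info_seeking", positive="Yes")


def toy_grouped():
    return GroupedBinomial.from_cohort(toy_grouped_cohort(), TOY_SPEC)


def trapezoid_loglik(beta0, sigma_u2, groups):
    """Dense numeric integration over u in [-10 sd, 10 sd] per group."""
    sd = np.sqrt(sigma_u2)
    u = np.linspace(-10 * sd, 10 * sd, 400_001)
    total = 0.0
    for ys in groups:
        p = expit(beta0 + u)
        f = np.ones_like(u)
        for y in ys:
            f = f * (p if y else 1 - p)
        total += np.log(np.trapezoid(f * norm.pdf(u, 0, sd), u))
    return total


class TestMarginalLoglik:
    def test_matches_dense_integration_oracle(self):
        g = toy_grouped()
        ll = m.marginal_loglik(np.array([0.3]), 0.4, g, nodes=15)
        oracle = trapezoid_loglik(0.3, 0.4, [[1, 0, 1], [0, 0, 1]])
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_zero_variance_collapses_to_logistic(self):
        g = toy_grouped()
        y = np.array([1, 0, 1, 0, 0, 1])
        ll_plain = sm.Logit(y, np.ones((6, 1))).loglike(np.array([0.3]))
        assert m.marginal_loglik(np.array([0.3]), 0.0, g) == pytest.approx(
            ll_plain, abs=1e-10
        )

    def test_logistic_symmetry_under_outcome_flip(self):
        g = toy_grouped()
        df = toy_grouped_cohort().df.copy()
        df["online_info_seeking"] = df["online_info_seeking"].map(
            {"Yes": "No", "No": "Yes"}
        )
        g_flip = GroupedBinomial.from_cohort(
            m.CohortTable(df, "filtered"), TOY_SPEC
        )
        for s2 in (0.0, 0.4, 2.0):
            assert m.marginal_loglik(np.array([0.7]), s2, g) == pytest.approx(
                m.marginal_loglik(np.array([-0.7]), s2, g_flip), abs=1e-10
            )

    def test_quadrature_order_converged(self, analytic_cohort, codebook, schema):
        _, cohort, _ = analytic_cohort
        spec = m.GlmmSpec.from_codebook(codebook, fixed_terms=("gender",))
        g = GroupedBinomial.from_cohort(cohort, spec)
        beta = np.array([-0.6, 0.4])
        for s2 in (0.05, 0.3, 1.5):
            assert m.marginal_loglik(beta, s2, g, nodes=15) == pytest.approx(
                m.marginal_loglik(beta, s2, g, nodes=25), abs=1e-6
            )

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            m.marginal_loglik(np.array([0.0]), -0.1, toy_grouped())


def simulate_binary_groups(n, n_groups, beta0, beta_x, sigma_u2, seed):
    """Direct simulation bypassing the survey codebook: one binary covariate
    constant within group, half the groups in each arm."""
    rng = np.random.default_rng(seed)
    g = rng.integers(0, n_groups, size=n)
    x = (g % 2).astype(float)
    u = rng.normal(0, np.sqrt(sigma_u2), size=n_groups)
    y = rng.random(n) < expit(beta0 + beta_x * x + u[g])
    df = pd.DataFrame(
        {
            "y": np.where(y, "1", "0"),
            "x": np.where(x == 1, "B", "A"),
            "stratum_id": [f"g{i:02d}" for i in g],
        }
    )
    spec = m.GlmmSpec(
        outcome="y", positive="1", fixed_terms=("x",),
        coding={"x": ("B",)}, references={"x": "A"},
    )
    return m.CohortTable(df, "filtered"), spec


class TestFitGlmm:
    def test_zero_variance_truth_hits_boundary(self):
        cohort, spec = simulate_binary_groups(2000, 40, -0.3, 0.6, 0.0, seed=9)
        fit = m.fit_glmm(spec, cohort)
        assert fit.sigma_u2 < 0.05
        assert abs(fit.beta[1] - 0.6) < 3 * fit.se_beta[1]

    def test_fixed_zero_variance_equals_logistic_mle(self):
        cohort, spec = simulate_binary_groups(1500, 30, -0.5, 0.8, 0.3, seed=2)
        fit = m.fit_glmm(spec, cohort, m.FitOptions(fix_sigma_u2=0.0))
        df = cohort.df
        y = (df["y"] == "1").to_numpy(int)
        X = np.column_stack([np.ones(len(df)), (df["x"] == "B").to_numpy(float)])
        res = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.beta, res.params, atol=1e-5)
        assert fit.loglik == pytest.approx(res.llf, abs=1e-6)

    def test_parameter_recovery(self):
        cohort, spec = simulate_binary_groups(4000, 48, -0.5, 0.8, 0.5, seed=31)
        fit = m.fit_glmm(spec, cohort)
        assert fit.converged
        assert abs(fit.beta[0] + 0.5) < 3 * fit.se_beta[0]
        assert abs(fit.beta[1] - 0.8) < 3 * fit.se_beta[1]
        g = GroupedBinomial.from_cohort(cohort, spec)
        ll_truth = m.marginal_loglik(np.array([-0.5, 0.8]), 0.5, g)
        assert fit.loglik >= ll_truth - 1e-6

    def test_single_stratum_unidentifiable(self):
        df = pd.DataFrame({"y": ["1", "0", "1"], "stratum_id": ["a"] * 3})
        spec = m.GlmmSpec(outcome="y", positive="1")
        with pytest.raises(ValueError, match="single stratum"):
            m.fit_glmm(spec, m.CohortTable(df, "filtered"))

    def test_constant_outcome_rejected(self):
        df = pd.DataFrame({"y": ["1"] * 6, "stratum_id": ["a", "b"] * 3})
        spec = m.GlmmSpec(outcome="y", positive="1")
        with pytest.raises(ValueError, match="no variation"):
            m.fit_glmm(spec, m.CohortTable(df, "filtered"))

    def test_objective_trace_is_monotone(self):
        cohort, spec = simulate_binary_groups(1000, 20, 0.0, 0.5, 0.4, seed=5)
        fit = m.fit_glmm(spec, cohort)
        trace = np.array(fit.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_matches_lme4_glmer(self, analytic_cohort, codebook, tmp_path):
        """Independent cross-check: same model in R's lme4 at nAGQ=15."""
        _, cohort, _ = analytic_cohort
        sub = m.CohortTable(cohort.df.iloc[:400].copy(), "filtered")
        spec = m.GlmmSpec.from_codebook(codebook, fixed_terms=("gender",))
        fit = m.fit_glmm(spec, sub)
        df = sub.df.assign(
            y=(sub.df["online_info_seeking"] == "Yes").astype(int),
            woman=(sub.df["gender"] == "Woman").astype(int),
        )[["y", "woman", "stratum_id"]]
        csv = tmp_path / "fixture.csv"
        df.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            "suppressMessages(library(lme4))\n"
            f'd <- read.csv("{csv}")\n'
            "f <- glmer(y ~ woman + (1|stratum_id), data=d, family=binomial, nAGQ=15)\n"
            'cat(sprintf("%.10f %.10f %.10f %.10f", fixef(f)[1], fixef(f)[2],'
            " VarCorr(f)$stratum_id[1], as.numeric(logLik(f))))\n"
        )
        out = subprocess.run(
            ["Rscript", str(rscript)], capture_output=True, text=True, check=True
        )
        b0, b1, s2, ll = map(float, out.stdout.split())
        assert fit.beta[0] == pytest.approx(b0, abs=1e-3)
        assert fit.beta[1] == pytest.approx(b1, abs=1e-3)
        assert fit.sigma_u2 == pytest.approx(s2, abs=1e-3)
        assert fit.loglik == pytest.approx(ll, abs=1e-4)


class TestRandomEffectPredictions:
    def test_mode_matches_grid_search_oracle(self):
        cohort, spec = simulate_binary_groups(60, 3, 0.2, 0.5, 0.6, seed=13)
        g = GroupedBinomial.from_cohort(cohort, spec)
        beta = np.array([0.2, 0.5])
        s2 = 0.6
        modes, _ = _posterior_modes(g.X @ beta, g, s2)
        grid = np.arange(-4.0, 4.0, 1e-4)
        eta = g.X @ beta
        for k in range(g.n_groups):
            sel = g.group_idx == k
            ll = (
                g.successes[sel] @ np.log(expit(eta[sel, None] + grid))
                + (g.trials - g.successes)[sel] @ np.log(expit(-(eta[sel, None] + grid)))
                - grid**2 / (2 * s2)
            )
            assert modes[k] == pytest.approx(grid[np.argmax(ll)], abs=1e-3)

    def test_balanced_stratum_has_zero_deviation(self):
        # two mirror-image strata: intercept fits both exactly, EB residual ~ 0
        df = pd.DataFrame(
            {
                "y": ["1", "0"] * 10 + ["0", "1"] * 10,
                "stratum_id": ["a"] * 20 + ["b"] * 20,
            }
        )
        cohort = m.CohortTable(df, "filtered")
        spec = m.GlmmSpec(outcome="y", positive="1")
        fit = m.fit_glmm(spec, cohort)
        for p in m.predict_random_effects(fit, cohort):
            assert abs(p.eb_value) < 1e-6

    def test_shrinkage_toward_zero_and_monotone_in_n(self):
        # same 75% empirical rate, different stratum sizes -> smaller shrinks more
        rows = []
        for sid, reps in [("big", 40), ("small", 8)]:
            rows += [{"y": "1", "stratum_id": sid}] * (3 * reps)
            rows += [{"y": "0", "stratum_id": sid}] * reps
        rows += [{"y": "1", "stratum_id": "c"}] * 10 + [
            {"y": "0", "stratum_id": "c"}
        ] * 30
        cohort = m.CohortTable(pd.DataFrame(rows), "filtered")
        spec = m.GlmmSpec(outcome="y", positive="1")
        fit = m.fit_glmm(spec, cohort)
        preds = {p.stratum_id: p for p in m.predict_random_effects(fit, cohort)}
        raw_resid = np.log(3.0) - fit.beta[0]  # empirical log-odds minus intercept
        for sid in ("big", "small"):
            assert 0 < preds[sid].eb_value < raw_resid
        assert preds["small"].eb_value < preds["big"].eb_value
        assert preds["small"].posterior_sd <= np.sqrt(fit.sigma_u2) * 1.01

    def test_empty_strata_are_prior_only(self, analytic_cohort, schema, codebook):
        _, cohort, strata = analytic_cohort
        spec = m.GlmmSpec.from_codebook(codebook)
        fit = m.fit_glmm(spec, cohort)
        all_ids = [s.id for s in strata]
        preds = {
            p.stratum_id: p
            for p in m.predict_random_effects(fit, cohort, all_stratum_ids=all_ids)
        }
        assert len(preds) == 192
        empty = [s.id for s in strata if not s.observed]
        assert empty, "fixture should leave some cells empty"
        for sid in empty:
            assert preds[sid].eb_value == 0.0
            assert not preds[sid].data_informed
            assert preds[sid].posterior_sd == pytest.approx(np.sqrt(fit.sigma_u2))


class TestWaldTable:
    def _fit_with(self, beta, se):
        return m.GlmmFit(
            spec=TOY_SPEC, term_names=[f"t{i}" for i in range(len(beta))],
            beta=np.asarray(beta, float), se_beta=np.asarray(se, float),
            cov_beta=np.diag(np.asarray(se, float) ** 2), sigma_u2=0.1,
            loglik=-1.0, converged=True, at_boundary=False,
            separation_suspected=False, n_obs=10, n_groups=2, quad_nodes=15,
            n_iter=3, message="ok",
        )

    def test_direct_arithmetic(self):
        table = m.wald_or_table(self._fit_with([0.0], [0.1]), level=0.95)
        assert table.loc[0, "OR"] == pytest.approx(1.0)
        assert table.loc[0, "lower"] == pytest.approx(np.exp(-1.959964 * 0.1), rel=1e-6)
        assert round(table.loc[0, "lower"], 2) == 0.82
        assert round(table.loc[0, "upper"], 2) == 1.22

    def test_vanishing_se_collapses_interval(self):
        table = m.wald_or_table(self._fit_with([np.log(2)], [1e-12]))
        assert table.loc[0, "lower"] == pytest.approx(2.0, abs=1e-6)
        assert table.loc[0, "upper"] == pytest.approx(2.0, abs=1e-6)

    def test_missing_se_yields_unavailable_bounds(self):
        table = m.wald_or_table(self._fit_with([0.5], [np.nan]))
        assert np.isnan(table.loc[0, "lower"]) and np.isnan(table.loc[0, "upper"])
        assert table.loc[0, "OR"] == pytest.approx(np.exp(0.5))

    def test_coverage_of_true_or(self):
        # the published-style effect stays inside its 95% CI in most replicates
        hits = 0
        for seed in range(40):
            cohort, spec = simulate_binary_groups(1200, 30, -0.5, 0.8, 0.3, seed=seed)
            fit = m.fit_glmm(spec, cohort)
            t = m.wald_or_table(fit)
            row = t[t["term"] == "x[B]"].iloc[0]
            hits += row["lower"] <= np.exp(0.8) <= row["upper"]
        assert hits >= 34  # >= 85% of 40
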
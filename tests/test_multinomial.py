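"""Multinomial logit estimation and Rubin pooling to relative risk ratios."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import careclust as cc
from careclust.errors import ConfigurationError
from careclust.multinomial import ModelSpec, _pool_fits, encode_design, fit_multinomial


def _simulate_multinomial(rng, X, beta):
    """Draw outcomes from a baseline-category logit with coefficients beta
    ((K-1) x p, category 0 as reference)."""
    eta = np.hstack([np.zeros((X.shape[0], 1)), X @ beta.T])
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    return (p.cumsum(axis=1) < rng.random(len(X))[:, None]).sum(axis=1)


class TestFitMultinomial:
    def test_two_by_two_closed_form(self):
        """Binary outcome, binary predictor, counts (10,20;40,30): the
        log-RRR equals the closed-form log odds ratio log(0.375)."""
        y = np.array([0] * 10 + [1] * 20 + [0] * 40 + [1] * 30)
        x = np.array([0] * 30 + [1] * 70)
        X = np.column_stack([np.ones(100), x])
        fit = fit_multinomial(X, y, ModelSpec(outcome_reference=0))
        assert fit.coef[0, 1] == pytest.approx(math.log(30 * 10 / (20 * 40)), abs=1e-8)

    def test_null_predictor_recovery(self):
        """A predictor independent of the outcome yields coefficients within
        3 standard errors of zero."""
        rng = np.random.default_rng(2)
        n = 10_000
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        y = rng.choice(3, size=n, p=[0.5, 0.3, 0.2])
        fit = fit_multinomial(X, y, ModelSpec(outcome_reference=0))
        p = X.shape[1]
        for c in range(2):
            se = np.sqrt(fit.cov[c * p + 1, c * p + 1])
            assert abs(fit.coef[c, 1]) < 3 * se

    def test_reference_category_invariance(self):
        rng = np.random.default_rng(3)
        n = 1500
        X = np.column_stack([np.ones(n), rng.random(n), rng.integers(0, 2, n)])
        beta = np.array([[0.3, 0.8, -0.5], [-0.2, -0.4, 0.7]])
        y = _simulate_multinomial(rng, X, beta)
        f0 = fit_multinomial(X, y, ModelSpec(outcome_reference=0))
        f2 = fit_multinomial(X, y, ModelSpec(outcome_reference=2))
        p0 = f0.predict_proba(X)
        p2 = f2.predict_proba(X)
        aligned = np.zeros_like(p2)
        for j, cat in enumerate(f2.categories):
            aligned[:, f0.categories.index(cat)] = p2[:, j]
        assert np.abs(p0 - aligned).max() < 1e-10

    def test_agrees_with_direct_likelihood_maximisation(self):
        """Coefficients match a brute-force numerical maximisation of the
        multinomial log-likelihood (3 outcomes, 2 predictors, n=200)."""
        rng = np.random.default_rng(4)
        n = 200
        X = np.column_stack([np.ones(n), rng.random(n), rng.integers(0, 2, n).astype(float)])
        beta = np.array([[0.5, -1.0, 0.8], [-0.3, 0.6, -0.4]])
        y = _simulate_multinomial(rng, X, beta)
        fit = fit_multinomial(X, y, ModelSpec(outcome_reference=0))

        def negll(flat):
            b = flat.reshape(2, 3)
            eta = np.hstack([np.zeros((n, 1)), X @ b.T])
            lse = np.log(np.exp(eta - eta.max(1, keepdims=True)).sum(1)) + eta.max(1)
            return -(eta[np.arange(n), y] - lse).sum()

        res = minimize(negll, np.zeros(6), method="BFGS", options={"gtol": 1e-10})
        assert np.abs(fit.coef.reshape(-1) - res.x).max() < 1e-5

    def test_agrees_with_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        n = 800
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        beta = np.array([[0.2, 0.9], [-0.5, 0.4]])
        y = _simulate_multinomial(rng, X, beta)
        fit = fit_multinomial(X, y, ModelSpec(outcome_reference=0))
        sm_fit = statsmodels.MNLogit(y, X).fit(disp=0, method="newton")
        assert np.abs(fit.coef - sm_fit.params.T).max() < 1e-6

    def test_missing_category_rejected(self):
        X = np.ones((10, 1))
        y = np.zeros(10, dtype=int)
        with pytest.raises(ConfigurationError):
            fit_multinomial(X, y, ModelSpec(outcome_reference=0))


class TestEncodeDesign:
    def test_reference_levels_dropped_and_interactions_present(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "gender": rng.choice(["female", "male", "gender-diverse"], 200),
                "age_group": rng.choice(["12-14", "15-17", "18-20", "21-25"], 200),
                "indigenous_flag": rng.choice(["no", "yes"], 200),
                "cald_flag": rng.choice(["no", "yes"], 200),
                "irsad_tertile": rng.choice(["low", "mid", "high"], 200),
                "remoteness": rng.choice(
                    ["major city", "inner regional", "outer regional/remote"], 200
                ),
            }
        )
        X, names = encode_design(df, ModelSpec())
        assert names[0] == "(intercept)"
        assert "gender[female]" not in names
        assert "gender[gender-diverse]" in names
        assert any(":" in n for n in names)  # IRSAD x remoteness interaction

    def test_unknown_reference_rejected(self):
        df = pd.DataFrame({"gender": ["male", "male"]})
        spec = ModelSpec(predictors={"gender": "female"}, interactions=())
        with pytest.raises(ConfigurationError):
            encode_design(df, spec)


class TestFitPooled:
    def test_identical_imputations_equal_single_fit(self, separable_imps):
        imps, truth, cohort = separable_imps
        episodes = cohort.episodes.set_index("episode_id").loc[
            list(imps.episode_ids)
        ].reset_index()
        spec = ModelSpec(indicator_terms=("distress",))
        pooled = cc.fit_pooled(episodes, truth, spec, imps=imps)
        # completed copies are identical, so between-variance vanishes
        for s in pooled.entries.values():
            assert s.between_variance == pytest.approx(0.0, abs=1e-20)

    def test_hand_worked_rubin_pool(self):
        """m=2 with estimates (0.9, 1.1) and variances 0.04: pooled
        estimate 1.0, total variance 0.04 + 1.5 * 0.02 = 0.07."""
        s = cc.pool_scalars([0.9, 1.1], [0.04, 0.04])
        assert s.estimate == pytest.approx(1.0)
        assert s.total_variance == pytest.approx(0.07)

    def test_pct_increase_rendering(self):
        assert cc.pct_increase(3.41) == pytest.approx(241.0)

    def test_planted_gender_effect_point_recovery(self):
        """One large cohort: the pooled RRR for gender-diverse membership in
        the highest-complexity cluster sits near the planted 3.41."""
        cohort = cc.generate_cohort(cc.GeneratorConfig(n_episodes=30_000, seed=6))
        pooled = cc.fit_pooled(
            cohort.episodes, cohort.episodes["true_cluster"].to_numpy()
        )
        rrr, lo, hi = pooled.rrr(4, "gender[gender-diverse]")
        assert lo < 3.41 < hi
        assert rrr == pytest.approx(3.41, rel=0.25)
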
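"""Multinomial logistic regression of cluster membership on risk factors,
with Rubin's-rules pooling to relative risk ratios (RRRs).

The model is a baseline-category logit: for outcome categories
c = 2..K against reference category 1,

    log P(y = c | x) / P(y = 1 | x) = x' beta_c

Exponentiated coefficients are relative risk ratios comparing membership
in category c with the reference category.  Estimation is full Newton
maximisation of the multinomial log-likelihood with step-halving, the
observed-information covariance, and an optional ridge retry under
quasi-separation.  When predictors involve multiply imputed quantities the
model is fitted per completed dataset and coefficients pooled on the log
scale by Rubin's rules; otherwise a single fit is reported as a degenerate
pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StageError
from .impute import ImputationSet, PooledScalar, pool_scalars

log = logging.getLogger(__name__)

MAX_ITER = 200
GRAD_TOL = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """Design of the cluster-membership regression.

    ``predictors`` maps categorical episode-level fields to their declared
    reference level (dummy encoding, no standardisation).  ``interactions``
    lists pairs entered as full interactions — by default socio-economic
    tertile and remoteness are considered jointly.  ``indicator_terms``
    names indicator columns (imputed quantities) entering the design, which
    triggers per-imputation fitting and pooling.
    """

    outcome_reference: int | str = 1
    predictors: dict[str, str] = field(
        default_factory=lambda: {
            "gender": "female",
            "age_group": "12-14",
            "indigenous_flag": "no",
            "cald_flag": "no",
            "irsad_tertile": "low",
            "remoteness": "major city",
        }
    )
    interactions: tuple[tuple[str, str], ...] = (("irsad_tertile", "remoteness"),)
    indicator_terms: tuple[str, ...] = ()


@dataclass
class MultinomialFit:
    """A single maximum-likelihood fit."""

    coef: np.ndarray                  # (K-1) x p
    cov: np.ndarray                   # ((K-1) p) x ((K-1) p), observed information
    categories: list                  # outcome categories, reference first
    term_names: list[str]
    loglik: float
    n_iter: int
    converged: bool

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = np.hstack([np.zeros((X.shape[0], 1)), X @ self.coef.T])
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)


def encode_design(
    table: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Dummy-encode predictors (declared reference levels dropped) with an
    intercept, plus any configured full interactions."""
    cols: dict[str, np.ndarray] = {"(intercept)": np.ones(len(table))}
    level_dummies: dict[str, dict[str, np.ndarray]] = {}
    for fld, ref in spec.predictors.items():
        if fld not in table.columns:
            raise ConfigurationError(f"predictor field {fld!r} not in table")
        vals = table[fld].astype(str).to_numpy()
        levels = [l for l in pd.unique(vals)]
        if ref not in levels:
            raise ConfigurationError(f"reference level {ref!r} absent for {fld!r}")
        level_dummies[fld] = {}
        for lvl in sorted(l for l in levels if l != ref):
            dummy = (vals == lvl).astype(float)
            cols[f"{fld}[{lvl}]"] = dummy
            level_dummies[fld][lvl] = dummy
    for f1, f2 in spec.interactions:
        for l1, d1 in level_dummies.get(f1, {}).items():
            for l2, d2 in level_dummies.get(f2, {}).items():
                cols[f"{f1}[{l1}]:{f2}[{l2}]"] = d1 * d2
    for term in spec.indicator_terms:
        if term not in table.columns:
            raise ConfigurationError(f"indicator term {term!r} not in table")
        cols[term] = table[term].to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    # drop empty/collinear interaction columns to keep the design full rank
    keep = [j for j in range(X.shape[1]) if j == 0 or X[:, j].any()]
    X = X[:, keep]
    names = [names[j] for j in keep]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConfigurationError("design matrix is rank deficient after encoding")
    return X, names


def _loglik(eta_full: np.ndarray, Y: np.ndarray) -> float:
    a = eta_full.max(axis=1, keepdims=True)
    lse = a[:, 0] + np.log(np.exp(eta_full - a).sum(axis=1))
    return float((eta_full[np.arange(len(Y)), Y] - lse).sum())


def fit_multinomial(
    design: np.ndarray,
    labels: Sequence,
    spec: Optional[ModelSpec] = None,
    term_names: Optional[list[str]] = None,
    ridge: float = 0.0,
) -> MultinomialFit:
    """Newton maximum-likelihood fit of the baseline-category logit.

    Iterates full Newton steps with step-halving (the log-likelihood never
    decreases) until the gradient infinity-norm drops below 1e-8, then
    takes one extra step to polish; covariance is the inverse observed
    information.  Quasi-separation (runaway coefficients) triggers a ridge
    1e-6 retry with a warning.
    """
    X = np.asarray(design, dtype=float)
    y_raw = np.asarray(labels)
    ref = spec.outcome_reference if spec is not None else 1
    cats = sorted(pd.unique(y_raw).tolist())
    if ref not in cats:
        raise ConfigurationError(f"outcome reference {ref!r} absent from labels")
    cats = [ref] + [c for c in cats if c != ref]
    if min(np.sum(y_raw == c) for c in cats) < 1:
        raise ConfigurationError("every outcome category needs >= 1 observation")
    code = {c: j for j, c in enumerate(cats)}
    y = np.array([code[c] for c in y_raw])
    n, p = X.shape
    K = len(cats)
    if K < 2:
        raise ConfigurationError("need at least 2 outcome categories")

    beta = np.zeros((K - 1, p))
    Y_ind = np.zeros((n, K - 1))
    for c in range(1, K):
        Y_ind[:, c - 1] = y == c

    def eta_full(b):
        return np.hstack([np.zeros((n, 1)), X @ b.T])

    ll = _loglik(eta_full(beta), y) - 0.5 * ridge * (beta**2).sum()
    n_iter = 0
    converged = False
    for n_iter in range(1, MAX_ITER + 1):
        eta = eta_full(beta)
        eta_s = eta - eta.max(axis=1, keepdims=True)
        P = np.exp(eta_s)
        P /= P.sum(axis=1, keepdims=True)
        Pc = P[:, 1:]
        G = X.T @ (Y_ind - Pc)                      # p x (K-1)
        grad = G.T.reshape(-1) - ridge * beta.reshape(-1)
        gnorm = np.abs(grad).max()
        if gnorm < GRAD_TOL and converged:
            break
        if gnorm < GRAD_TOL:
            converged = True                        # polish with one more step
        H = np.zeros(((K - 1) * p, (K - 1) * p))
        for a in range(K - 1):
            for b in range(a, K - 1):
                w = Pc[:, a] * ((a == b) - Pc[:, b])
                blk = X.T @ (X * w[:, None])
                H[a * p:(a + 1) * p, b * p:(b + 1) * p] = blk
                if b != a:
                    H[b * p:(b + 1) * p, a * p:(a + 1) * p] = blk
        H += ridge * np.eye((K - 1) * p)
        try:
            step = np.linalg.solve(H, grad).reshape(K - 1, p)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0].reshape(K - 1, p)
        # step-halving: never accept a decrease in the penalised likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _loglik(eta_full(cand), y) - 0.5 * ridge * (cand**2).sum()
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        ll = ll_new
    else:
        if not converged:
            raise StageError(
                "fit_multinomial",
                f"no convergence in {MAX_ITER} iterations (grad norm {gnorm:.2e})",
            )

    if ridge == 0.0 and np.abs(beta).max() > 15.0:
        log.warning("quasi-separation suspected (|coef| > 15); ridge 1e-6 retry")
        return fit_multinomial(X, labels, spec, term_names, ridge=1e-6)

    # observed information at the final estimate
    eta = eta_full(beta)
    eta_s = eta - eta.max(axis=1, keepdims=True)
    P = np.exp(eta_s)
    P /= P.sum(axis=1, keepdims=True)
    Pc = P[:, 1:]
    H = np.zeros(((K - 1) * p, (K - 1) * p))
    for a in range(K - 1):
        for b in range(a, K - 1):
            w = Pc[:, a] * ((a == b) - Pc[:, b])
            blk = X.T @ (X * w[:, None])
            H[a * p:(a + 1) * p, b * p:(b + 1) * p] = blk
            if b != a:
                H[b * p:(b + 1) * p, a * p:(a + 1) * p] = blk
    H += ridge * np.eye((K - 1) * p)
    cov = np.linalg.inv(H)
    return MultinomialFit(
        coef=beta,
        cov=cov,
        categories=cats,
        term_names=term_names or [f"x{j}" for j in range(p)],
        loglik=ll,
        n_iter=n_iter,
        converged=True,
    )


@dataclass
class PooledModel:
    """Rubin-pooled multinomial model, expressed as RRRs with 95% CIs."""

    entries: dict[tuple, PooledScalar]   # (outcome category, term) -> log-RRR scale
    categories: list
    term_names: list[str]
    m: int

    def rrr(self, category, term: str) -> tuple[float, float, float]:
        s = self.entries[(category, term)]
        return float(np.exp(s.estimate)), float(np.exp(s.ci_low)), float(np.exp(s.ci_high))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (cat, term), s in self.entries.items():
            rows.append(
                {
                    "outcome": cat,
                    "term": term,
                    "log_rrr": s.estimate,
                    "se": np.sqrt(s.total_variance),
                    "rrr": np.exp(s.estimate),
                    "ci_low": np.exp(s.ci_low),
                    "ci_high": np.exp(s.ci_high),
                    "pct_change": (np.exp(s.estimate) - 1.0) * 100.0,
                }
            )
        return pd.DataFrame(rows)


def pct_increase(rrr: float) -> float:
    """Render a relative risk ratio as a percentage change (3.41 -> 241%)."""
    return (rrr - 1.0) * 100.0


def _pool_fits(fits: list[MultinomialFit]) -> PooledModel:
    f0 = fits[0]
    K1, p = f0.coef.shape
    entries: dict[tuple, PooledScalar] = {}
    for c in range(K1):
        cat = f0.categories[c + 1]
        for j in range(p):
            flat = c * p + j
            ests = [f.coef[c, j] for f in fits]
            vars_ = [f.cov[flat, flat] for f in fits]
            if len(fits) == 1:
                se = np.sqrt(vars_[0])
                from scipy import stats as _st

                half = _st.norm.ppf(0.975) * se
                entries[(cat, f0.term_names[j])] = PooledScalar(
                    estimate=float(ests[0]),
                    within_variance=float(vars_[0]),
                    between_variance=0.0,
                    total_variance=float(vars_[0]),
                    df=float("inf"),
                    ci_low=float(ests[0] - half),
                    ci_high=float(ests[0] + half),
                    m=1,
                )
            else:
                entries[(cat, f0.term_names[j])] = pool_scalars(ests, vars_)
    return PooledModel(
        entries=entries,
        categories=f0.categories,
        term_names=f0.term_names,
        m=len(fits),
    )


def fit_pooled(
    covariates: pd.DataFrame,
    labels: Sequence,
    spec: Optional[ModelSpec] = None,
    imps: Optional[ImputationSet] = None,
) -> PooledModel:
    """Fit the cluster-membership model, pooling over imputations if needed.

    Cluster labels come fixed from the consensus solution and covariates
    are complete, so the default specification requires a single fit; when
    ``spec.indicator_terms`` bring imputed indicator columns into the
    design, the model is fitted per completed dataset and pooled
    coordinate-wise by Rubin's rules on the log-RRR scale.
    """
    spec = spec or ModelSpec()
    labels = np.asarray(labels)
    if len(labels) != len(covariates):
        raise ConfigurationError("labels and covariates must be row-aligned")

    if spec.indicator_terms:
        if imps is None:
            raise ConfigurationError("indicator_terms require an ImputationSet")
        fits = []
        for c in imps.completed:
            tab = covariates.copy()
            for term in spec.indicator_terms:
                j = imps.indicator_names.index(term)
                tab[term] = c[:, j]
            X, names = encode_design(tab, spec)
            fits.append(fit_multinomial(X, labels, spec, names))
        cats0 = fits[0].categories
        if any(f.categories != cats0 for f in fits):
            raise StageError("fit_pooled", "outcome category absent in some imputation")
        return _pool_fits(fits)

    X, names = encode_design(covariates, spec)
    return _pool_fits([fit_multinomial(X, labels, spec, names)])
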
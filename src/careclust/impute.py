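"""Chained-equation multiple imputation of binary indicators, with
Rubin's-rules pooling used throughout the downstream estimators.

Each missing indicator cell is drawn from a ridge-stabilised logistic
model conditional on the other indicators (plus optional complete
covariates), cycled over a fixed number of sweeps in ascending-missingness
order.  Conditional models are fitted on a bootstrap resample of the
observed rows so that parameter uncertainty propagates into
between-imputation variance (an approximately "proper" scheme); observed
cells are never modified.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .errors import ConfigurationError, PoolingError
from .indicators import IndicatorMatrix

log = logging.getLogger(__name__)

DEFAULT_M = 20
DEFAULT_SWEEPS = 10
DEFAULT_RIDGE = 1e-4


@dataclass
class ImputationSet:
    """m completed copies of an indicator matrix sharing row identity."""

    completed: list[np.ndarray]          # each n x p, int8, fully observed
    episode_ids: np.ndarray
    indicator_names: tuple[str, ...]
    m: int
    rng_state: dict

    def __post_init__(self):
        if self.m != len(self.completed):
            raise ConfigurationError("m does not match number of completed datasets")

    @property
    def n(self) -> int:
        return self.completed[0].shape[0]

    def mean_matrix(self) -> np.ndarray:
        """Cell-wise mean of the completed datasets (in [0, 1])."""
        return np.mean([c.astype(float) for c in self.completed], axis=0)

    def mean_burden(self) -> np.ndarray:
        """Per-episode indicator count averaged over imputations."""
        return self.mean_matrix().sum(axis=1)


def _fit_conditional(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator, ridge: float, bootstrap: bool
) -> LogisticRegression:
    if bootstrap:
        idx = rng.integers(0, len(y), size=len(y))
        # a bootstrap draw may lose a class; retry a few times then fall back
        for _ in range(10):
            if len(np.unique(y[idx])) == 2:
                break
            idx = rng.integers(0, len(y), size=len(y))
        else:
            idx = np.arange(len(y))
        X, y = X[idx], y[idx]
    model = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=200)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(X, y)
        except ConvergenceWarning:
            log.warning(
                "conditional model did not converge at ridge %.1e; "
                "retrying with strong ridge", ridge,
            )
            model = LogisticRegression(C=1.0, solver="lbfgs", max_iter=500)
            model.fit(X, y)
    return model


def impute(
    m_in: IndicatorMatrix,
    m_count: int = DEFAULT_M,
    covariates: Optional[pd.DataFrame] = None,
    seed: Optional[int] = None,
    n_sweeps: int = DEFAULT_SWEEPS,
    ridge: float = DEFAULT_RIDGE,
    bootstrap: bool = True,
) -> ImputationSet:
    """Multiply impute missing indicator cells by chained equations.

    Parameters
    ----------
    m_in
        Indicator matrix after the exclusion filter (no all-missing rows).
    m_count
        Number of completed datasets (default 20).
    covariates
        Optional complete auxiliary table (row-aligned); dummy-encoded and
        offered to every conditional model.
    seed
        Master seed; per-imputation substreams are derived deterministically.
    """
    if m_count < 1:
        raise ConfigurationError("m_count must be >= 1")
    values, mask = m_in.values, m_in.observed_mask
    n, p = values.shape
    if not mask.any(axis=1).all():
        raise ConfigurationError("all-missing rows present; run exclusion_filter first")
    obs_count = mask.sum(axis=0)
    if (obs_count == 0).any():
        bad = [m_in.indicator_names[j] for j in np.flatnonzero(obs_count == 0)]
        raise ConfigurationError(f"indicators never observed, cannot impute: {bad}")

    if covariates is not None:
        if len(covariates) != n:
            raise ConfigurationError("covariates must be row-aligned with the matrix")
        Z = pd.get_dummies(covariates, drop_first=True).to_numpy(dtype=float)
    else:
        Z = np.empty((n, 0))

    missing_cols = np.flatnonzero((~mask).any(axis=0))
    order = missing_cols[np.argsort((~mask[:, missing_cols]).sum(axis=0))]

    root = np.random.SeedSequence(seed)
    children = root.spawn(m_count)
    completed: list[np.ndarray] = []
    for child in children:
        rng = np.random.default_rng(child)
        filled = values.astype(np.int8).copy()
        # initialise missing cells from observed prevalence
        for j in missing_cols:
            miss = ~mask[:, j]
            prev = values[mask[:, j], j].mean()
            filled[miss, j] = (rng.random(miss.sum()) < prev).astype(np.int8)
        for _ in range(n_sweeps if len(missing_cols) else 0):
            for j in order:
                miss = ~mask[:, j]
                y_obs = values[mask[:, j], j]
                if y_obs.min() == y_obs.max():
                    # constant among observed: draw from a smoothed prevalence
                    prev = (y_obs.sum() + 0.5) / (len(y_obs) + 1.0)
                    filled[miss, j] = (rng.random(miss.sum()) < prev).astype(np.int8)
                    continue
                others = [c for c in range(p) if c != j]
                X = np.hstack([filled[:, others].astype(float), Z])
                model = _fit_conditional(X[mask[:, j]], y_obs, rng, ridge, bootstrap)
                prob = model.predict_proba(X[miss])[:, 1]
                filled[miss, j] = (rng.random(miss.sum()) < prob).astype(np.int8)
        completed.append(filled)

    return ImputationSet(
        completed=completed,
        episode_ids=m_in.episode_ids,
        indicator_names=m_in.indicator_names,
        m=m_count,
        rng_state={
            "seed": seed,
            "n_sweeps": n_sweeps,
            "ridge": ridge,
            "bootstrap": bootstrap,
            "spawn_keys": [list(c.spawn_key) for c in children],
        },
    )


# ---------------------------------------------------------------------------
# Rubin's rules


@dataclass(frozen=True)
class PooledScalar:
    """A scalar pooled across imputations by Rubin's rules.

    ``total_variance = within + (1 + 1/m) * between``; the confidence
    interval uses a t reference with Barnard–Rubin adjusted degrees of
    freedom (the large-sample form when no complete-data df is supplied).
    """

    estimate: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float
    ci_low: float
    ci_high: float
    m: int


def pool_scalars(
    estimates: Sequence[float],
    variances: Sequence[float],
    df_com: Optional[float] = None,
    alpha: float = 0.05,
) -> PooledScalar:
    """Combine per-imputation estimates and variances by Rubin's rules."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2:
        raise PoolingError("Rubin pooling needs at least 2 imputations")
    if len(u) != m or (u < 0).any():
        raise PoolingError("variances must be non-negative and match estimates")

    qbar = q.mean()
    ubar = u.mean()
    b = q.var(ddof=1)
    t = ubar + (1.0 + 1.0 / m) * b

    if b <= 0 or t <= 0:
        df = np.inf
    else:
        lam = (1.0 + 1.0 / m) * b / t
        df_old = (m - 1) / lam**2
        if df_com is None or not np.isfinite(df_com):
            df = df_old
        else:
            df_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)

    crit = stats.norm.ppf(1 - alpha / 2) if np.isinf(df) else stats.t.ppf(1 - alpha / 2, df)
    half = crit * np.sqrt(t)
    return PooledScalar(
        estimate=float(qbar),
        within_variance=float(ubar),
        between_variance=float(b),
        total_variance=float(t),
        df=float(df),
        ci_low=float(qbar - half),
        ci_high=float(qbar + half),
        m=m,
    )
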
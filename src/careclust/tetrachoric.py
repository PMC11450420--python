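"""Tetrachoric correlation networks between binary complexity indicators.

The tetrachoric correlation infers the correlation of a latent bivariate
normal from a 2x2 table of two dichotomised variables: thresholds are set
from the margins via the inverse normal, and rho is the value whose
bivariate-normal rectangle probability matches the observed joint cell —
which is also the maximum-likelihood value for fixed margins, since the
multinomial likelihood is unimodal in rho along that constraint.

Pairwise correlations are estimated per completed dataset, pooled across
imputations on the Fisher-z scale, and embedded in two dimensions by
classical (Torgerson) multidimensional scaling for the network plot.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import owens_t

from .errors import ConfigurationError
from .impute import ImputationSet

log = logging.getLogger(__name__)

RHO_BOUND = 0.999


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for a standard bivariate normal with correlation rho.

    Evaluated through Owen's T function, which is accurate to near machine
    precision (well inside the 1e-10 tolerance the likelihood needs).
    """
    if rho >= 1.0:
        return float(stats.norm.cdf(min(h, k)))
    if rho <= -1.0:
        return float(max(0.0, stats.norm.cdf(h) + stats.norm.cdf(k) - 1.0))
    if rho == 0.0:
        return float(stats.norm.cdf(h) * stats.norm.cdf(k))
    if h == 0.0 and k == 0.0:
        return 0.25 + np.arcsin(rho) / (2.0 * np.pi)
    # continuous limits: nudge exact zeros off the axis
    if h == 0.0:
        h = 1e-15
    if k == 0.0:
        k = 1e-15
    r = np.sqrt(1.0 - rho * rho)
    a_h = (k - rho * h) / (h * r)
    a_k = (h - rho * k) / (k * r)
    beta = 0.0 if h * k > 0 else 0.5
    val = (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - owens_t(h, a_h)
        - owens_t(k, a_k)
        - beta
    )
    return float(min(1.0, max(0.0, val)))


def tetrachoric(counts: np.ndarray) -> float:
    """Maximum-likelihood tetrachoric rho from a 2x2 table.

    ``counts[a, b]`` is the number of observations with first variable = a
    and second = b (a, b in {0, 1}).  Zero cells are corrected by adding
    0.5 to every cell; the estimate is clamped to [-0.999, 0.999].  A
    degenerate margin (a variable entirely constant) returns NaN.
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ConfigurationError("counts must be a non-negative 2x2 table")
    if t[1, :].sum() == 0 or t[0, :].sum() == 0 or t[:, 1].sum() == 0 or t[:, 0].sum() == 0:
        return float("nan")
    if (t == 0).any():
        t = t + 0.5
    n = t.sum()
    if n < 10:
        raise ConfigurationError("table total must be >= 10 after correction")
    p_a0 = t[0, :].sum() / n
    p_b0 = t[:, 0].sum() / n
    p00 = t[0, 0] / n
    h = stats.norm.ppf(p_a0)  # threshold: P(X <= h) = P(A = 0)
    k = stats.norm.ppf(p_b0)

    f = lambda rho: bvn_cdf(h, k, rho) - p00
    lo, hi = -RHO_BOUND, RHO_BOUND
    if f(lo) >= 0:
        return -RHO_BOUND
    if f(hi) <= 0:
        return RHO_BOUND
    return float(brentq(f, lo, hi, xtol=1e-10))


def pair_table(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """2x2 contingency table of two 0/1 vectors."""
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = int(np.sum((x == 0) & (y == 0)))
    return np.array([[n00, n01], [n10, n11]], dtype=float)


def tetrachoric_matrix(values: np.ndarray) -> np.ndarray:
    """All-pairs tetrachoric matrix of a fully observed 0/1 matrix."""
    n, p = values.shape
    v = values.astype(np.int64)
    n11 = v.T @ v
    col1 = v.sum(axis=0)
    rho = np.eye(p)
    for i_ in range(p):
        for j_ in range(i_ + 1, p):
            a = n11[i_, j_]
            b = col1[i_] - a           # x=1, y=0
            c = col1[j_] - a           # x=0, y=1
            d = n - col1[i_] - col1[j_] + a
            r = tetrachoric(np.array([[d, c], [b, a]], dtype=float))
            rho[i_, j_] = rho[j_, i_] = r
    return rho


@dataclass
class TetraNetwork:
    """Pooled tetrachoric correlation network with an MDS layout."""

    rho: np.ndarray                  # p x p, symmetric, unit diagonal
    pooled_from: int
    layout: np.ndarray               # p x 2, centred
    edge_list: pd.DataFrame          # source, target, rho
    indicator_names: tuple[str, ...]


def pooled_matrix(imps: ImputationSet) -> TetraNetwork:
    """Per-imputation tetrachoric matrices pooled on the Fisher-z scale.

    Pairs undefined (degenerate margin) in more than half the imputations
    are flagged missing (NaN) in the pooled matrix; the diagonal is forced
    to 1.  The layout and edge list are derived from the pooled matrix.
    """
    if imps.m < 2:
        raise ConfigurationError("pooling needs at least 2 imputations")
    mats = np.stack([tetrachoric_matrix(c) for c in imps.completed])
    z = np.arctanh(np.clip(mats, -RHO_BOUND, RHO_BOUND))
    n_def = np.isfinite(z).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pooled = np.tanh(np.nanmean(z, axis=0))
    pooled[n_def <= imps.m / 2] = np.nan
    np.fill_diagonal(pooled, 1.0)

    names = imps.indicator_names
    layout = mds_layout(np.nan_to_num(pooled, nan=0.0))
    rows = [
        {"source": names[a], "target": names[b], "rho": pooled[a, b]}
        for a in range(len(names))
        for b in range(a + 1, len(names))
    ]
    return TetraNetwork(
        rho=pooled,
        pooled_from=imps.m,
        layout=layout,
        edge_list=pd.DataFrame(rows),
        indicator_names=names,
    )


def nearest_psd(rho: np.ndarray, warn_change: float = 0.1) -> np.ndarray:
    """Eigenvalue-clipping repair to the nearest positive-semidefinite
    correlation-like matrix (diagonal re-normalised to 1)."""
    sym = (rho + rho.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() >= -1e-12:
        return sym
    w = np.clip(w, 0.0, None)
    fixed = v @ np.diag(w) @ v.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    change = np.abs(fixed - sym).max()
    if change > warn_change:
        log.warning("PSD repair changed an entry by %.3f (> %.2f)", change, warn_change)
    return fixed


def mds_layout(rho: np.ndarray) -> np.ndarray:
    """Classical (Torgerson) 2-d scaling of the correlation structure.

    Dissimilarity d_ij = sqrt(2 (1 - rho_ij)) after PSD repair; the layout
    is centred at the origin and its reflection fixed so item 1 has
    non-negative coordinates.
    """
    p = rho.shape[0]
    if rho.shape != (p, p) or np.abs(rho - rho.T).max() > 1e-8:
        raise ConfigurationError("rho must be square and symmetric")
    fixed = nearest_psd(rho)
    d2 = 2.0 * (1.0 - fixed)          # squared distances
    J = np.eye(p) - np.ones((p, p)) / p
    B = -0.5 * J @ d2 @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:2]
    lam = np.clip(w[idx], 0.0, None)
    coords = v[:, idx] * np.sqrt(lam)[None, :]
    coords = coords - coords.mean(axis=0, keepdims=True)
    for c in range(2):
        if coords[0, c] < 0:
            coords[:, c] = -coords[:, c]
    return coords


def kruskal_stress(rho: np.ndarray, coords: np.ndarray) -> float:
    """Stress-0 of a layout against the rho-derived dissimilarities."""
    target = np.sqrt(np.clip(2.0 * (1.0 - rho), 0.0, None))
    diff = coords[:, None, :] - coords[None, :, :]
    got = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices_from(rho, k=1)
    num = ((got[iu] - target[iu]) ** 2).sum()
    den = (target[iu] ** 2).sum()
    return float(np.sqrt(num / den)) if den > 0 else 0.0
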
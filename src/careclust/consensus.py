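"""K-means consensus clustering integrated over multiple imputations.

For every completed dataset and every resampling replicate, a random
subsample of episodes is clustered with k-means; pairwise co-clustering
counts are normalised by co-sampling counts into a consensus matrix.  The
final partition comes from an average-linkage hierarchical cut of the
consensus dissimilarity, with clusters relabelled in increasing order of
mean indicator burden (cluster 1 = lowest complexity).  The proportion of
ambiguous clustering (PAC) and the consensus CDF serve as
cluster-number diagnostics, advisory rather than binding: the number of
groups actually used may be chosen on substantive grounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .errors import ConfigurationError
from .impute import ImputationSet

log = logging.getLogger(__name__)

DEFAULT_R = 100
DEFAULT_SUBSAMPLE = 0.8
PAC_WINDOW = (0.1, 0.9)


@dataclass
class ConsensusResult:
    """Consensus matrix, diagnostics and severity-ordered labels for one k."""

    k: int
    consensus: np.ndarray            # n x n in [0, 1], symmetric, unit diagonal
    labels: np.ndarray               # length n, values 1..k, severity ordered
    pac: float
    cdf_points: pd.DataFrame         # columns: value, cdf
    settings: dict


def _pac(consensus: np.ndarray, window: tuple[float, float] = PAC_WINDOW) -> float:
    iu = np.triu_indices_from(consensus, k=1)
    vals = consensus[iu]
    lo, hi = window
    return float(np.mean((vals > lo) & (vals < hi)))


def _consensus_cdf(consensus: np.ndarray, n_points: int = 101) -> pd.DataFrame:
    iu = np.triu_indices_from(consensus, k=1)
    vals = np.sort(consensus[iu])
    grid = np.linspace(0.0, 1.0, n_points)
    cdf = np.searchsorted(vals, grid, side="right") / len(vals)
    return pd.DataFrame({"value": grid, "cdf": cdf})


def _severity_order(labels: np.ndarray, burden: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by increasing mean indicator burden."""
    uniq = np.unique(labels)
    means = np.array([burden[labels == c].mean() for c in uniq])
    order = uniq[np.argsort(means, kind="stable")]
    remap = {int(c): r + 1 for r, c in enumerate(order)}
    return np.array([remap[int(c)] for c in labels], dtype=int)


def consensus_kmeans(
    imps: ImputationSet,
    k: int,
    R: int = DEFAULT_R,
    p: float = DEFAULT_SUBSAMPLE,
    seed: Optional[int] = None,
) -> ConsensusResult:
    """Consensus k-means over an imputation set.

    For each of the ``m`` completed datasets and each of ``R`` replicates,
    ``ceil(p * n)`` episodes are subsampled without replacement and
    clustered by k-means (k-means++ initialisation, indicators as 0/1
    numerics, Euclidean metric).  consensus(i, j) = co-clustered count /
    co-sampled count; never co-sampled pairs receive the global mean
    consensus (logged).  Final labels: average-linkage hierarchical
    clustering on 1 - consensus cut at ``k``, then severity ordering.
    """
    n = imps.n
    if not 2 <= k <= max(2, n // 10):
        raise ConfigurationError(f"need 2 <= k <= n/10, got k={k} with n={n}")
    if not 0.5 <= p <= 1.0:
        raise ConfigurationError("subsample fraction p must lie in [0.5, 1]")
    if R < 10:
        raise ConfigurationError("need R >= 10 resamples per imputation")

    rng = np.random.default_rng(seed)
    n_sub = int(np.ceil(p * n))
    conn = np.zeros((n, n), dtype=np.float32)
    cosamp = np.zeros((n, n), dtype=np.float32)

    for i_imp in range(imps.m):
        data = imps.completed[i_imp].astype(np.float32)
        samp = np.zeros((n, R), dtype=np.float32)
        memb = np.zeros((n, R * k), dtype=np.float32)
        for r in range(R):
            idx = rng.choice(n, size=n_sub, replace=False)
            sub = data[idx]
            for attempt in range(2):
                km = KMeans(
                    n_clusters=k,
                    init="k-means++",
                    n_init=1,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                ).fit(sub)
                lab = km.labels_
                if len(np.unique(lab)) == k or attempt == 1:
                    break
                log.warning("empty cluster in base run; re-seeding once")
            samp[idx, r] = 1.0
            for c in np.unique(lab):
                memb[idx[lab == c], r * k + c] = 1.0
        conn += memb @ memb.T
        cosamp += samp @ samp.T

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(cosamp > 0, conn / np.maximum(cosamp, 1e-12), np.nan)
    never = ~np.isfinite(consensus)
    np.fill_diagonal(never, False)
    if never.any():
        fill = float(np.nanmean(consensus[np.triu_indices(n, k=1)]))
        log.warning(
            "%d never-co-sampled pairs filled with global mean consensus %.3f",
            int(never.sum() // 2), fill,
        )
        consensus[never] = fill
    consensus = np.clip((consensus + consensus.T) / 2.0, 0.0, 1.0).astype(float)
    np.fill_diagonal(consensus, 1.0)

    dist = squareform(1.0 - consensus, checks=False)
    tree = linkage(dist, method="average")
    raw = fcluster(tree, t=k, criterion="maxclust")
    labels = _severity_order(raw, imps.mean_burden())

    return ConsensusResult(
        k=k,
        consensus=consensus,
        labels=labels,
        pac=_pac(consensus),
        cdf_points=_consensus_cdf(consensus),
        settings={
            "R": R,
            "p": p,
            "seed": seed if (seed is None or isinstance(seed, int)) else str(seed),
            "m": imps.m,
            "pac_window": PAC_WINDOW,
        },
    )


NO_STRUCTURE_PAC = 0.3


def select_k(
    imps: ImputationSet,
    k_range: Sequence[int] = range(2, 7),
    R: int = DEFAULT_R,
    p: float = DEFAULT_SUBSAMPLE,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, int, bool]:
    """PAC / consensus-CDF diagnostics over a range of cluster numbers.

    Returns ``(diagnostics, recommended_k, no_structure)``.  The
    recommendation is the PAC-minimising k; callers may override it on
    substantive grounds (the chosen k is recorded separately from the
    recommendation by the pipeline).  ``no_structure`` is flagged when even
    the best PAC stays above ``NO_STRUCTURE_PAC`` — no k yields a stable
    split.
    """
    ks = list(k_range)
    if not ks:
        raise ConfigurationError("k_range is empty")
    ss = np.random.SeedSequence(seed).spawn(len(ks))
    rows = []
    for k, child in zip(ks, ss):
        res = consensus_kmeans(imps, k, R=R, p=p, seed=child)
        rows.append({"k": k, "pac": res.pac})
    diag = pd.DataFrame(rows)
    recommended = int(diag.loc[diag["pac"].idxmin(), "k"])
    no_structure = bool(diag["pac"].min() > NO_STRUCTURE_PAC)
    if no_structure:
        log.warning("no stable cluster structure: min PAC %.3f", diag["pac"].min())
    return diag, recommended, no_structure


def compare_partitions(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted Rand index between two partitions (permutation invariant)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ConfigurationError("partitions must have equal length")
    return float(adjusted_rand_score(a, b))
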
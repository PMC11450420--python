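"""Reporting surfaces: cohort accounting, cluster characteristics and
centre-level prevalence distributions.

All percentages are recomputed from integer counts at render time and
printed to one decimal (half-up); rounded values are never stored
internally.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .indicators import IndicatorMatrix
from .simulate import Cohort

LOW_N_CENTRE = 20


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (5 always rounds away from zero)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class CohortAccounting:
    """Printed cohort arithmetic: totals, exclusions and cluster shares."""

    n_total: int
    n_excluded: int
    n_retained: int
    cluster_n: dict[int, int]

    def __post_init__(self):
        if self.n_total != self.n_excluded + self.n_retained:
            raise ConfigurationError("accounting must satisfy total = excluded + retained")
        if self.cluster_n and sum(self.cluster_n.values()) != self.n_retained:
            raise ConfigurationError("cluster counts must sum to n_retained")

    @property
    def pct_excluded(self) -> float:
        return round_half_up(100.0 * self.n_excluded / self.n_total)

    def cluster_pct(self, c: int) -> float:
        return round_half_up(100.0 * self.cluster_n[c] / self.n_retained)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_excluded": self.n_excluded,
            "n_retained": self.n_retained,
            "pct_excluded": self.pct_excluded,
            "clusters": {
                str(c): {"n": n, "pct": self.cluster_pct(c)}
                for c, n in sorted(self.cluster_n.items())
            },
        }


def cohort_accounting(filter_report: dict, labels: Sequence[int]) -> CohortAccounting:
    """Assemble the accounting from the exclusion report and final labels."""
    labels = np.asarray(labels)
    if len(labels) != filter_report["n_retained"]:
        raise ConfigurationError("labels length must equal n_retained")
    counts = {int(c): int((labels == c).sum()) for c in np.unique(labels)}
    return CohortAccounting(
        n_total=int(filter_report["n_total"]),
        n_excluded=int(filter_report["n_excluded"]),
        n_retained=int(filter_report["n_retained"]),
        cluster_n=counts,
    )


def characteristics_by_cluster(
    cohort: Cohort,
    labels: Sequence[int],
    matrix: Optional[IndicatorMatrix] = None,
    episode_ids: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Per-cluster characteristics table.

    Covers size, demographic composition, visit-count mean/median and —
    when the (post-filter) indicator matrix is supplied — the mean number
    of complexity indicators with missing entries counted as not reporting
    the factor.
    """
    labels = np.asarray(labels)
    if episode_ids is None and matrix is not None:
        episode_ids = matrix.episode_ids
    if episode_ids is None:
        raise ConfigurationError("need episode_ids (or a matrix) aligned with labels")
    episodes = cohort.episodes.set_index("episode_id").loc[list(episode_ids)]

    rows = []
    for c in np.unique(labels):
        sel = labels == c
        sub = episodes[sel]
        row = {
            "cluster": int(c),
            "n": int(sel.sum()),
            "mean_visits": float(sub["n_visits"].mean()),
            "median_visits": float(sub["n_visits"].median()),
        }
        for fld in ("gender", "age_group", "indigenous_flag", "cald_flag",
                    "remoteness", "irsad_tertile"):
            for lvl, cnt in sub[fld].value_counts().items():
                row[f"{fld}={lvl}_pct"] = round_half_up(100.0 * cnt / len(sub))
        if matrix is not None:
            # missing treated as not reporting the factor
            counts = (matrix.values[sel] * matrix.observed_mask[sel]).sum(axis=1)
            row["mean_indicator_count"] = float(counts.mean())
        rows.append(row)
    return pd.DataFrame(rows)


def centre_distribution(
    labels: Sequence[int], centre_ids: Sequence, n_density: int = 101
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-centre cluster prevalences plus plot-ready density curves.

    Returns ``(prevalence, density)``: per centre and cluster the share of
    the centre's episodes in that cluster (with a low-n flag for centres
    under 20 episodes, retained), and per cluster a Gaussian-kernel density
    (Silverman bandwidth) of the across-centre prevalence distribution
    together with its min/max range.
    """
    labels = np.asarray(labels)
    centres = np.asarray(centre_ids, dtype=object)
    if len(labels) != len(centres):
        raise ConfigurationError("labels and centre ids must be row-aligned")
    uniq_centres = pd.unique(centres)
    if len(uniq_centres) < 2:
        raise ConfigurationError("centre distribution needs >= 2 centres")
    clusters = np.unique(labels)

    rows = []
    for ctr in uniq_centres:
        sel = centres == ctr
        n_c = int(sel.sum())
        for c in clusters:
            rows.append(
                {
                    "centre_id": ctr,
                    "cluster": int(c),
                    "n_episodes": n_c,
                    "prevalence": float((labels[sel] == c).mean()),
                    "low_n": n_c < LOW_N_CENTRE,
                }
            )
    prevalence = pd.DataFrame(rows)

    dens_rows = []
    grid = np.linspace(0.0, 1.0, n_density)
    for c in clusters:
        vals = prevalence.loc[prevalence["cluster"] == c, "prevalence"].to_numpy()
        if len(vals) >= 2 and vals.std() > 0:
            kde = stats.gaussian_kde(vals, bw_method="silverman")
            dens = kde(grid)
        else:
            dens = np.zeros_like(grid)
        for x, d in zip(grid, dens):
            dens_rows.append(
                {
                    "cluster": int(c),
                    "prevalence": float(x),
                    "density": float(d),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                }
            )
    return prevalence, pd.DataFrame(dens_rows)
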
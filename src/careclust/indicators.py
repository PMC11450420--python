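"""Mapping of raw episode/visit fields to 13 binary complexity indicators.

Each indicator is a predicate on per-visit fields (a scale threshold, an
ordinal cut or a category-set membership), aggregated over the episode by
an any-visit OR: the indicator is 1 if its rule fires at any visit, 0 if
the source was measured at one or more visits and never fired, and missing
(mask false) when the source was never measured during the episode.

The default indicator set reconstructs the study's published definitions
from the available thresholds (very high distress K10 > 30, low
functioning SOFAS <= 60, quality-of-life and staging cuts exposed as
parameters); it is a reconstruction, not a verbatim data dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, StageError
from .simulate import Cohort, INDICATOR_NAMES, SEVERE_DIAGNOSES, STAGE_LEVELS


@dataclass(frozen=True)
class IndicatorDefinition:
    """One binary complexity indicator.

    ``rule`` maps the visit table to a nullable boolean series (NA where
    the source fields are unmeasured at that visit); aggregation over
    visits is fixed to any-visit OR.
    """

    name: str
    source_fields: tuple[str, ...]
    description: str
    rule: Callable[[pd.DataFrame], pd.Series]


@dataclass
class IndicatorMatrix:
    """n x 13 binary indicator values with an explicit missingness mask."""

    episode_ids: np.ndarray            # length n, object
    values: np.ndarray                 # n x p, int8 in {0, 1}
    observed_mask: np.ndarray          # n x p, bool
    indicator_names: tuple[str, ...]

    def __post_init__(self):
        n, p = self.values.shape
        if self.observed_mask.shape != (n, p) or len(self.episode_ids) != n:
            raise ConfigurationError("inconsistent IndicatorMatrix shapes")
        if len(self.indicator_names) != p:
            raise ConfigurationError("indicator_names length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with paired ``<name>__observed`` columns."""
        data = {"episode_id": self.episode_ids}
        for j, name in enumerate(self.indicator_names):
            data[name] = self.values[:, j]
            data[f"{name}__observed"] = self.observed_mask[:, j].astype(int)
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IndicatorMatrix":
        names = tuple(
            c for c in df.columns if c != "episode_id" and not c.endswith("__observed")
        )
        values = df[list(names)].to_numpy(dtype=np.int8)
        mask = df[[f"{n}__observed" for n in names]].to_numpy(dtype=bool)
        return cls(df["episode_id"].to_numpy(object), values, mask, names)


def _scale_rule(fld: str, predicate) -> Callable[[pd.DataFrame], pd.Series]:
    def rule(visits: pd.DataFrame) -> pd.Series:
        col = visits[fld]
        fired = pd.Series(predicate(col), index=visits.index).astype("boolean")
        fired[col.isna()] = pd.NA
        return fired

    return rule


def _flag_rule(fld: str) -> Callable[[pd.DataFrame], pd.Series]:
    def rule(visits: pd.DataFrame) -> pd.Series:
        return visits[fld].astype("boolean")

    return rule


def _category_rule(fld: str, members: Sequence[str]) -> Callable[[pd.DataFrame], pd.Series]:
    members = set(members)

    def rule(visits: pd.DataFrame) -> pd.Series:
        col = visits[fld]
        fired = col.isin(members).astype("boolean")
        fired[col.isna()] = pd.NA
        return fired

    return rule


def default_indicator_set(
    mlt_cut: float = 40.0,
    stage_cut: str = "2",
    severe_diagnoses: Sequence[str] = SEVERE_DIAGNOSES,
) -> list[IndicatorDefinition]:
    """The 13 default complexity indicator definitions.

    Scale thresholds: K10 strictly greater than 30 (very high distress),
    SOFAS of 60 or below (moderate-to-severe impairment), MyLifeTracker
    below ``mlt_cut`` (low quality of life; the instrument defines no
    published cut, so it is a parameter).  "Later stage of illness" is a
    clinician staging at or beyond ``stage_cut`` on the 1a..4 ordinal.
    """
    if stage_cut not in STAGE_LEVELS:
        raise ConfigurationError(f"stage_cut must be one of {STAGE_LEVELS}")
    stage_rank = {s: r for r, s in enumerate(STAGE_LEVELS)}
    later = {s for s in STAGE_LEVELS if stage_rank[s] >= stage_rank[stage_cut]}

    defs = [
        IndicatorDefinition(
            "distress", ("k10_total",), "very high psychological distress (K10 > 30)",
            _scale_rule("k10_total", lambda c: c > 30),
        ),
        IndicatorDefinition(
            "low_qol", ("mlt_total",), f"low quality of life (MLT < {mlt_cut:g})",
            _scale_rule("mlt_total", lambda c: c < mlt_cut),
        ),
        IndicatorDefinition(
            "low_functioning", ("sofas",), "low functioning (SOFAS <= 60)",
            _scale_rule("sofas", lambda c: c <= 60),
        ),
        IndicatorDefinition(
            "later_stage", ("stage",), f"later stage of illness (stage >= {stage_cut})",
            _category_rule("stage", later),
        ),
        IndicatorDefinition(
            "severe_disorder", ("diagnosis_codes",),
            "diagnosis of a severe/complex disorder",
            _category_rule("diagnosis_codes", severe_diagnoses),
        ),
        IndicatorDefinition(
            "self_harm", ("presenting_issue",),
            "self-harm or suicidality as primary presenting issue",
            _category_rule("presenting_issue", ("self-harm/suicidality",)),
        ),
        IndicatorDefinition(
            "aod_treatment", ("aod_treatment_flag",),
            "alcohol-and-other-drug treatment issue", _flag_rule("aod_treatment_flag"),
        ),
        IndicatorDefinition(
            "trauma", ("trauma_flag",), "trauma history", _flag_rule("trauma_flag"),
        ),
        IndicatorDefinition(
            "housing", ("housing_issue_flag",), "housing issues",
            _flag_rule("housing_issue_flag"),
        ),
        IndicatorDefinition(
            "neet", ("neet_flag",), "not in employment, education or training",
            _flag_rule("neet_flag"),
        ),
        IndicatorDefinition(
            "eet_issue", ("eet_issue_flag",),
            "education/employment engagement issue", _flag_rule("eet_issue_flag"),
        ),
        IndicatorDefinition(
            "benefits", ("benefits_flag",), "receiving government benefits",
            _flag_rule("benefits_flag"),
        ),
        IndicatorDefinition(
            "cooccurring", ("cooccurring_flag",), "co-occurring difficulties",
            _flag_rule("cooccurring_flag"),
        ),
    ]
    assert tuple(d.name for d in defs) == INDICATOR_NAMES
    return defs


def derive_indicators(
    cohort: Cohort, defs: Optional[list[IndicatorDefinition]] = None
) -> IndicatorMatrix:
    """Apply indicator rules per visit and aggregate by any-visit OR."""
    if cohort.n_episodes == 0:
        raise ConfigurationError("cohort is empty")
    if defs is None:
        defs = default_indicator_set(mlt_cut=cohort.config.mlt_cut)
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ConfigurationError("indicator names must be unique")

    visits = cohort.visits
    episode_ids = cohort.episodes["episode_id"].to_numpy(object)
    n = len(episode_ids)
    pos = pd.Series(np.arange(n), index=episode_ids)
    visit_ep = pos[visits["episode_id"]].to_numpy()

    values = np.zeros((n, len(defs)), dtype=np.int8)
    mask = np.zeros((n, len(defs)), dtype=bool)
    for j, d in enumerate(defs):
        for fld in d.source_fields:
            if fld not in visits.columns:
                raise SchemaError(f"indicator {d.name!r} needs missing field {fld!r}")
        fired = d.rule(visits)
        obs = fired.notna().to_numpy()
        hit = fired.fillna(False).to_numpy(dtype=bool)
        mask[:, j] = np.bincount(visit_ep[obs], minlength=n) > 0
        values[:, j] = (np.bincount(visit_ep[obs & hit], minlength=n) > 0).astype(np.int8)

    return IndicatorMatrix(episode_ids, values, mask, tuple(names))


def exclusion_filter(m: IndicatorMatrix) -> tuple[IndicatorMatrix, dict]:
    """Drop episodes missing every indicator; report the accounting.

    Mirrors the analytic-sample rule of omitting episodes with all
    complexity indicators unmeasured.  Idempotent; the report satisfies
    n_total = n_excluded + n_retained.
    """
    keep = m.observed_mask.any(axis=1)
    n_total = m.n
    n_retained = int(keep.sum())
    report = {
        "n_total": n_total,
        "n_excluded": n_total - n_retained,
        "n_retained": n_retained,
        "pct_excluded": 100.0 * (n_total - n_retained) / n_total if n_total else 0.0,
    }
    if n_retained == 0:
        raise StageError("exclusion_filter", "no episodes retain any observed indicator")
    out = IndicatorMatrix(
        m.episode_ids[keep], m.values[keep], m.observed_mask[keep], m.indicator_names
    )
    return out, report


def prevalence_by_group(m: IndicatorMatrix, grouping: Sequence) -> pd.DataFrame:
    """Indicator prevalence among observed entries, per group.

    Returns one row per (group, indicator) with the observed-cell
    denominator; groups with no observed entries get NaN prevalence, never
    an implicit zero.
    """
    grouping = np.asarray(grouping, dtype=object)
    if len(grouping) != m.n:
        raise ConfigurationError("grouping length must match the indicator matrix")
    rows = []
    for g in pd.unique(grouping):
        sel = grouping == g
        obs = m.observed_mask[sel]
        val = m.values[sel]
        n_obs = obs.sum(axis=0)
        n_yes = (val * obs).sum(axis=0)
        for j, name in enumerate(m.indicator_names):
            rows.append(
                {
                    "group": g,
                    "indicator": name,
                    "n_observed": int(n_obs[j]),
                    "n_yes": int(n_yes[j]),
                    "prevalence": (n_yes[j] / n_obs[j]) if n_obs[j] else np.nan,
                }
            )
    return pd.DataFrame(rows)
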
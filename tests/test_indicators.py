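"""Indicator mapping: thresholds, any-visit aggregation, exclusion filter,
group prevalences."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import careclust as cc
from careclust.errors import SchemaError, StageError
from careclust.indicators import IndicatorMatrix
from careclust.simulate import (
    Cohort,
    FLAG_FIELDS,
    GeneratorConfig,
    INDICATOR_NAMES,
)


def _toy_cohort(visit_rows: list[dict]) -> Cohort:
    """Build a cohort from sparse per-visit dicts (absent fields -> NA)."""
    episode_ids = sorted({r["episode_id"] for r in visit_rows})
    base = {
        "k10_total": np.nan,
        "sofas": np.nan,
        "mlt_total": np.nan,
        "stage": None,
        "diagnosis_codes": None,
        "presenting_issue": None,
        **{f: pd.NA for f in FLAG_FIELDS},
    }
    visits = pd.DataFrame([{**base, **r} for r in visit_rows])
    for f in FLAG_FIELDS:
        visits[f] = visits[f].astype("boolean")
    episodes = pd.DataFrame(
        {
            "episode_id": episode_ids,
            "person_id": episode_ids,
            "centre_id": "C000",
            "gender": "female",
            "age_group": "15-17",
            "indigenous_flag": "no",
            "cald_flag": "no",
            "remoteness": "major city",
            "irsad_tertile": "low",
            "n_visits": [sum(r["episode_id"] == e for r in visit_rows) for e in episode_ids],
            "true_cluster": 1,
        }
    )
    return Cohort(episodes=episodes, visits=visits, config=GeneratorConfig())


class TestDefaultIndicatorSet:
    def test_thirteen_definitions(self):
        defs = cc.default_indicator_set()
        assert len(defs) == 13
        assert tuple(d.name for d in defs) == INDICATOR_NAMES

    @pytest.mark.parametrize(
        "field,value,name,expected",
        [
            ("k10_total", 31, "distress", 1),
            ("k10_total", 30, "distress", 0),
            ("sofas", 60, "low_functioning", 1),
            ("sofas", 61, "low_functioning", 0),
            ("mlt_total", 39, "low_qol", 1),
            ("mlt_total", 40, "low_qol", 0),
            ("stage", "2", "later_stage", 1),
            ("stage", "1b", "later_stage", 0),
            ("diagnosis_codes", "bipolar", "severe_disorder", 1),
            ("diagnosis_codes", "anxiety", "severe_disorder", 0),
        ],
    )
    def test_threshold_boundaries(self, field, value, name, expected):
        cohort = _toy_cohort([{"episode_id": "E1", field: value}])
        mat = cc.derive_indicators(cohort)
        j = list(mat.indicator_names).index(name)
        assert mat.observed_mask[0, j]
        assert mat.values[0, j] == expected


class TestDeriveIndicators:
    def test_any_visit_or(self):
        cohort = _toy_cohort(
            [
                {"episode_id": "E1", "k10_total": 25},
                {"episode_id": "E1", "k10_total": 35},
                {"episode_id": "E1", "k10_total": 28},
            ]
        )
        mat = cc.derive_indicators(cohort)
        assert mat.values[0, 0] == 1

    def test_never_measured_is_missing(self):
        cohort = _toy_cohort([{"episode_id": "E1", "k10_total": 12, "sofas": 55}])
        mat = cc.derive_indicators(cohort)
        names = list(mat.indicator_names)
        assert mat.values[0, names.index("low_functioning")] == 1
        assert mat.values[0, names.index("distress")] == 0
        others = [j for j, n in enumerate(names) if n not in ("distress", "low_functioning")]
        assert not mat.observed_mask[0, others].any()
        assert mat.observed_mask[0, names.index("distress")]

    def test_unknown_field_raises_named_schema_error(self):
        cohort = _toy_cohort([{"episode_id": "E1", "k10_total": 12}])
        cohort.visits = cohort.visits.drop(columns=["sofas"])
        with pytest.raises(SchemaError, match="sofas"):
            cc.derive_indicators(cohort)

    def test_matches_independent_groupby_oracle(self, default_cohort):
        """Each derived indicator equals a direct pandas re-derivation
        (per-visit predicate + groupby any) on a cohort with missingness."""
        mat = cc.derive_indicators(default_cohort)
        visits = default_cohort.visits
        order = pd.Index(mat.episode_ids)
        fired = visits["k10_total"] > 30
        observed = visits["k10_total"].notna()
        grp_obs = observed.groupby(visits["episode_id"]).any().reindex(order, fill_value=False)
        grp_val = (
            (fired & observed).groupby(visits["episode_id"]).any().reindex(order, fill_value=False)
        )
        assert np.array_equal(mat.observed_mask[:, 0], grp_obs.to_numpy())
        assert np.array_equal(mat.values[:, 0].astype(bool), grp_val.to_numpy())

    @given(
        k10_a=st.integers(min_value=10, max_value=50),
        k10_b=st.integers(min_value=10, max_value=50),
    )
    def test_adding_a_visit_is_monotone(self, k10_a, k10_b):
        """Any-visit aggregation never flips an indicator 1 -> 0."""
        one = cc.derive_indicators(_toy_cohort([{"episode_id": "E1", "k10_total": k10_a}]))
        two = cc.derive_indicators(
            _toy_cohort(
                [
                    {"episode_id": "E1", "k10_total": k10_a},
                    {"episode_id": "E1", "k10_total": k10_b},
                ]
            )
        )
        assert two.values[0, 0] >= one.values[0, 0]
        assert two.observed_mask[0, 0] >= one.observed_mask[0, 0]


class TestExclusionFilter:
    def _matrix(self, mask_rows):
        n = len(mask_rows)
        ids = np.array([f"E{i+1}" for i in range(n)], dtype=object)
        values = np.zeros((n, 3), dtype=np.int8)
        mask = np.array(mask_rows, dtype=bool)
        return IndicatorMatrix(ids, values, mask, ("a", "b", "c"))

    def test_toy_enumeration(self):
        m = self._matrix(
            [[1, 1, 1], [0, 0, 0], [1, 0, 0], [0, 0, 0], [0, 1, 0]]
        )
        out, report = cc.exclusion_filter(m)
        assert list(out.episode_ids) == ["E1", "E3", "E5"]
        assert report == {
            "n_total": 5,
            "n_excluded": 2,
            "n_retained": 3,
            "pct_excluded": 40.0,
        }

    def test_noop_and_idempotence(self):
        m = self._matrix([[1, 0, 0], [0, 1, 0]])
        out, report = cc.exclusion_filter(m)
        assert report["n_excluded"] == 0
        again, report2 = cc.exclusion_filter(out)
        assert np.array_equal(again.values, out.values)
        assert report2["n_excluded"] == 0

    def test_conservation(self, default_cohort):
        mat = cc.derive_indicators(default_cohort)
        _, report = cc.exclusion_filter(mat)
        assert report["n_total"] == report["n_excluded"] + report["n_retained"]

    def test_empty_retained_is_fatal(self):
        m = self._matrix([[0, 0, 0], [0, 0, 0]])
        with pytest.raises(StageError, match="exclusion_filter"):
            cc.exclusion_filter(m)


class TestPrevalenceByGroup:
    def test_simple_and_observed_denominator(self):
        ids = np.array(["E1", "E2", "E3", "E4"], dtype=object)
        values = np.array([[1, 1], [1, 0], [0, 1], [1, 1]], dtype=np.int8)
        mask = np.array([[1, 1], [1, 1], [1, 0], [1, 0]], dtype=bool)
        m = IndicatorMatrix(ids, values, mask, ("a", "b"))
        tab = cc.prevalence_by_group(m, ["g"] * 4).set_index("indicator")
        assert tab.loc["a", "prevalence"] == 0.75
        assert tab.loc["b", "prevalence"] == 0.5
        assert tab.loc["b", "n_observed"] == 2

    def test_zero_observed_group_is_nan(self):
        ids = np.array(["E1", "E2"], dtype=object)
        m = IndicatorMatrix(
            ids,
            np.array([[1], [0]], dtype=np.int8),
            np.array([[1], [0]], dtype=bool),
            ("a",),
        )
        tab = cc.prevalence_by_group(m, ["g1", "g2"])
        row = tab[(tab["group"] == "g2")].iloc[0]
        assert np.isnan(row["prevalence"]) and row["n_observed"] == 0

    def test_overall_distress_prevalence_above_half(self, complete_cohort):
        """Under the default profiles, overall very-high-distress prevalence
        exceeds 50% (expected value 0.599 from the profile mixture)."""
        mat = cc.derive_indicators(complete_cohort)
        tab = cc.prevalence_by_group(mat, ["all"] * mat.n)
        prev = tab[tab["indicator"] == "distress"]["prevalence"].iloc[0]
        assert prev > 0.50
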
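"""Synthetic episode-of-care cohort generator.

Emulates a youth primary mental-health minimum data set: episodes of care
with per-visit clinical measures (K10 psychological distress, SOFAS
functioning, MyLifeTracker quality of life), clinician-rated illness stage,
diagnoses, presenting issues and psychosocial flags, plus demographics,
visit counts and service-centre identifiers.  A latent cluster structure
over 13 binary complexity indicators is planted so that every downstream
stage (indicator mapping, imputation, consensus clustering, network and
regression analysis) can be tested against known ground truth.

Episodes, not individuals, are the analysis unit; a small share of
individuals contributes more than one episode, mirroring routine service
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateSizeError

# ---------------------------------------------------------------------------
# Field vocabularies

AGE_GROUPS = ("12-14", "15-17", "18-20", "21-25")
GENDERS = ("female", "male", "gender-diverse")
REMOTENESS_LEVELS = ("major city", "inner regional", "outer regional/remote")
IRSAD_TERTILES = ("low", "mid", "high")
STAGE_LEVELS = ("1a", "1b", "2", "3", "4")
YESNO = ("no", "yes")

SEVERE_DIAGNOSES = ("psychotic", "bipolar", "personality", "neurodevelopmental")
OTHER_DIAGNOSES = ("anxiety", "depression", "adjustment", "other", "none")
PRESENTING_ISSUES = (
    "self-harm/suicidality",
    "mental health",
    "physical health",
    "situational",
    "vocational assistance",
    "alcohol/other drug",
)

#: The 13 binary complexity indicators, in canonical column order.
INDICATOR_NAMES = (
    "distress",          # K10 total > 30
    "low_qol",           # MyLifeTracker total below cut (default < 40)
    "low_functioning",   # SOFAS <= 60
    "later_stage",       # clinician stage >= 2
    "severe_disorder",   # psychotic / bipolar / personality / neurodevelopmental
    "self_harm",         # self-harm or suicidality as primary presenting issue
    "aod_treatment",     # alcohol-and-other-drug treatment issue
    "trauma",            # trauma history
    "housing",           # housing issues
    "neet",              # not in employment, education or training
    "eet_issue",         # education/employment engagement issue
    "benefits",          # receiving government benefits
    "cooccurring",       # co-occurring difficulties
)

#: Per-visit source field feeding each indicator (one-to-one by design).
INDICATOR_SOURCE_FIELDS = (
    "k10_total",
    "mlt_total",
    "sofas",
    "stage",
    "diagnosis_codes",
    "presenting_issue",
    "aod_treatment_flag",
    "trauma_flag",
    "housing_issue_flag",
    "neet_flag",
    "eet_issue_flag",
    "benefits_flag",
    "cooccurring_flag",
)

FLAG_FIELDS = (
    "aod_treatment_flag",
    "trauma_flag",
    "housing_issue_flag",
    "neet_flag",
    "eet_issue_flag",
    "benefits_flag",
    "cooccurring_flag",
)

CLUSTER_NAMES_4 = ("low", "distress", "psychosocial", "high")

# ---------------------------------------------------------------------------
# Default study conditions

#: Cluster shares of the four-group complexity solution.
DEFAULT_CLUSTER_PROPORTIONS = (0.398, 0.199, 0.218, 0.185)

#: Mean visits per episode by cluster (low, distress, psychosocial, high).
DEFAULT_VISIT_RATES = (4.0, 4.0, 2.9, 7.1)

#: Stylised within-cluster indicator prevalences for the four complexity
#: groups.  The qualitative pattern follows the published cluster
#: descriptions (distress group: high distress / low QoL / low functioning;
#: psychosocial group: additionally housing, NEET, education/employment and
#: benefits issues; high group: later stage, severe disorders, trauma and
#: co-occurring difficulties on top of clinical severity); exact
#: within-cluster percentages were not published, so these values are a
#: reconstruction, not empirical estimates.
DEFAULT_INDICATOR_PROFILES = np.array(
    [
        # dist  qol   func  stage sev   sh    aod   trau  hous  neet  eet   ben   cooc
        [0.25, 0.20, 0.20, 0.05, 0.03, 0.02, 0.02, 0.05, 0.03, 0.08, 0.08, 0.10, 0.10],
        [0.90, 0.85, 0.70, 0.15, 0.08, 0.08, 0.03, 0.15, 0.07, 0.12, 0.15, 0.15, 0.20],
        [0.75, 0.70, 0.60, 0.12, 0.07, 0.05, 0.06, 0.20, 0.45, 0.65, 0.70, 0.70, 0.30],
        [0.85, 0.80, 0.85, 0.70, 0.60, 0.25, 0.15, 0.70, 0.35, 0.40, 0.45, 0.45, 0.75],
    ]
)

#: Within-cluster residual dependence between indicator groups, applied via
#: a Gaussian copula so marginal prevalences still equal the profile rows.
#: Distress and low quality of life co-occur beyond what cluster membership
#: explains (overlapping constructs), as do the psychosocial-stressor items.
DEFAULT_RESIDUAL_BLOCKS: tuple[tuple[tuple[str, ...], float], ...] = (
    (("distress", "low_qol"), 0.45),
    (("housing", "neet", "eet_issue", "benefits"), 0.30),
)

DEFAULT_DEMOGRAPHIC_MARGINALS: dict[str, dict[str, float]] = {
    "gender": {"female": 0.60, "male": 0.36, "gender-diverse": 0.04},
    "age_group": {"12-14": 0.20, "15-17": 0.33, "18-20": 0.25, "21-25": 0.22},
    "indigenous_flag": {"no": 0.91, "yes": 0.09},
    "cald_flag": {"no": 0.80, "yes": 0.20},
    "remoteness": {"major city": 0.55, "inner regional": 0.35, "outer regional/remote": 0.10},
    "irsad_tertile": {"low": 0.35, "mid": 0.33, "high": 0.32},
}

#: Per-level log relative-risk tilts on cluster membership (length-K vectors,
#: first cluster is the reference).  The gender-diverse -> high-complexity
#: tilt of log 3.41 is the headline planted effect recovered by the
#: regression stage.
DEFAULT_DEMOGRAPHIC_EFFECTS: dict[str, dict[str, tuple[float, ...]]] = {
    "gender": {
        "male": (0.0, -0.5, 0.2, 0.0),
        "gender-diverse": (0.0, 0.5, 0.5, math.log(3.41)),
    },
    "age_group": {
        "15-17": (0.0, 0.2, 0.1, 0.2),
        "18-20": (0.0, 0.3, 0.5, 0.4),
        "21-25": (0.0, 0.3, 0.8, 0.5),
    },
    "indigenous_flag": {"yes": (0.0, 0.0, math.log(1.85), 0.3)},
    "cald_flag": {"yes": (0.0, -0.3, -0.3, -0.3)},
    "irsad_tertile": {
        "mid": (0.0, -0.15, -0.2, -0.2),
        "high": (0.0, -0.3, -0.45, -0.4),
    },
    "remoteness": {
        "inner regional": (0.0, 0.0, 0.2, 0.0),
        "outer regional/remote": (0.0, -0.1, -0.1, -0.2),
    },
}


def well_separated_profiles(k: int = 4, high: float = 0.95, low: float = 0.05) -> np.ndarray:
    """Indicator-profile matrix with large between-cluster separation.

    Clusters are assigned binary codewords over the first 12 indicators with
    pairwise Hamming distance 8 (for k <= 4), giving a mean absolute
    probability gap of at least 0.5 between every pair of profiles; the 13th
    indicator carries a severity gradient so cluster ordering by indicator
    burden stays well defined.  Used for cluster-recovery and k-selection
    experiments where the planted partition must be unambiguous.
    """
    if not 2 <= k <= 8:
        raise ConfigurationError("well_separated_profiles supports 2 <= k <= 8")
    codes4 = np.array(
        [
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
            [1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0],
            [1, 1, 1, 1, 0, 0, 0, 0, 1, 1, 1, 1],
            [0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1],
        ]
    )
    if k <= 4:
        codes = codes4[:k]
    else:
        # greedy random search for a code with large minimum pairwise distance
        rng = np.random.default_rng(20240918)
        best, best_d = None, -1
        for _ in range(2000):
            cand = rng.integers(0, 2, size=(k, 12))
            d = min(
                int(np.abs(cand[i] - cand[j]).sum())
                for i in range(k)
                for j in range(i + 1, k)
            )
            if d > best_d:
                best, best_d = cand, d
        codes = best
    profiles = np.where(codes == 1, high, low)
    severity = np.linspace(0.1, 0.9, k)[:, None]
    return np.hstack([profiles, severity])


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the published cohort geometry: four complexity
    groups with shares (0.398, 0.199, 0.218, 0.185), cluster-specific mean
    visit counts (4.0, 4.0, 2.9, 7.1), 14.1% of episodes missing every
    indicator, and services spread over 113 centres with heterogeneous
    cluster mixes.
    """

    n_episodes: int = 10_000
    cluster_proportions: tuple[float, ...] = DEFAULT_CLUSTER_PROPORTIONS
    indicator_profiles: Optional[np.ndarray] = None  # K x 13; defaults per K=4
    demographic_marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_DEMOGRAPHIC_MARGINALS
    )
    demographic_effects: Mapping[str, Mapping[str, Sequence[float]]] = field(
        default_factory=lambda: DEFAULT_DEMOGRAPHIC_EFFECTS
    )
    visit_rate_by_cluster: tuple[float, ...] = DEFAULT_VISIT_RATES
    visit_dispersion: float = 1.5
    residual_blocks: tuple[tuple[tuple[str, ...], float], ...] = DEFAULT_RESIDUAL_BLOCKS
    missing_rate_item: float = 0.10
    all_missing_fraction: float = 0.141
    mar_field: Optional[str] = None       # MCAR when None
    mar_level: Optional[str] = None
    mar_odds: float = 1.0
    n_centres: int = 113
    centre_mixing: float = 10.0
    repeat_person_fraction: float = 0.07
    mlt_cut: float = 40.0
    seed: int = 0

    @property
    def k(self) -> int:
        return len(self.cluster_proportions)

    def profiles(self) -> np.ndarray:
        if self.indicator_profiles is not None:
            return np.asarray(self.indicator_profiles, dtype=float)
        if self.k == 4:
            return DEFAULT_INDICATOR_PROFILES
        return well_separated_profiles(self.k)

    def validate(self) -> None:
        p = np.asarray(self.cluster_proportions, dtype=float)
        if not 2 <= self.k <= 8:
            raise ConfigurationError(f"need 2 <= K <= 8 clusters, got {self.k}")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ConfigurationError(
                f"cluster_proportions must sum to 1 (got {p.sum()!r})"
            )
        if (p < 0).any():
            raise ConfigurationError("cluster_proportions must be non-negative")
        prof = self.profiles()
        if prof.shape != (self.k, len(INDICATOR_NAMES)):
            raise ConfigurationError(
                f"indicator_profiles must be {self.k} x {len(INDICATOR_NAMES)}, "
                f"got {prof.shape}"
            )
        if ((prof < 0) | (prof > 1)).any():
            raise ConfigurationError("indicator_profiles entries must lie in [0, 1]")
        if len(self.visit_rate_by_cluster) != self.k:
            raise ConfigurationError("visit_rate_by_cluster must have one rate per cluster")
        if min(self.visit_rate_by_cluster) <= 0:
            raise ConfigurationError("visit rates must be positive")
        for rate, name in (
            (self.missing_rate_item, "missing_rate_item"),
            (self.all_missing_fraction, "all_missing_fraction"),
        ):
            if not 0 <= rate < 1:
                raise ConfigurationError(f"{name} must lie in [0, 1), got {rate}")
        seen: set[str] = set()
        for block, rho in self.residual_blocks:
            if not 0 <= rho < 1:
                raise ConfigurationError("residual block correlations must lie in [0, 1)")
            for name in block:
                if name not in INDICATOR_NAMES:
                    raise ConfigurationError(f"unknown indicator {name!r} in residual block")
                if name in seen:
                    raise ConfigurationError(f"indicator {name!r} in multiple residual blocks")
                seen.add(name)
        if self.n_centres < 1 or self.centre_mixing <= 0:
            raise ConfigurationError("need n_centres >= 1 and centre_mixing > 0")
        for fname, levels in self.demographic_effects.items():
            if fname not in self.demographic_marginals:
                raise ConfigurationError(f"effects reference unknown field {fname!r}")
            for level, vec in levels.items():
                if level not in self.demographic_marginals[fname]:
                    raise ConfigurationError(
                        f"effects reference unknown level {level!r} of {fname!r}"
                    )
                if len(vec) != self.k:
                    raise ConfigurationError(
                        f"effect vector for {fname}={level} must have length K={self.k}"
                    )

    def to_dict(self) -> dict:
        """Plain-python representation for YAML provenance dumps."""
        return {
            "n_episodes": self.n_episodes,
            "cluster_proportions": list(map(float, self.cluster_proportions)),
            "indicator_profiles": self.profiles().tolist(),
            "demographic_marginals": {
                f: {l: float(v) for l, v in lv.items()}
                for f, lv in self.demographic_marginals.items()
            },
            "demographic_effects": {
                f: {l: list(map(float, v)) for l, v in lv.items()}
                for f, lv in self.demographic_effects.items()
            },
            "residual_blocks": [
                {"indicators": list(block), "rho": float(r)}
                for block, r in self.residual_blocks
            ],
            "visit_rate_by_cluster": list(map(float, self.visit_rate_by_cluster)),
            "visit_dispersion": self.visit_dispersion,
            "missing_rate_item": self.missing_rate_item,
            "all_missing_fraction": self.all_missing_fraction,
            "mar_field": self.mar_field,
            "mar_level": self.mar_level,
            "mar_odds": self.mar_odds,
            "n_centres": self.n_centres,
            "centre_mixing": self.centre_mixing,
            "repeat_person_fraction": self.repeat_person_fraction,
            "mlt_cut": self.mlt_cut,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if d.get("indicator_profiles") is not None:
            d["indicator_profiles"] = np.asarray(d["indicator_profiles"], dtype=float)
        if "cluster_proportions" in d:
            d["cluster_proportions"] = tuple(d["cluster_proportions"])
        if "visit_rate_by_cluster" in d:
            d["visit_rate_by_cluster"] = tuple(d["visit_rate_by_cluster"])
        if "residual_blocks" in d:
            d["residual_blocks"] = tuple(
                (tuple(b["indicators"]), b["rho"]) for b in d["residual_blocks"]
            )
        if "demographic_effects" in d:
            d["demographic_effects"] = {
                f: {l: tuple(v) for l, v in lv.items()}
                for f, lv in d["demographic_effects"].items()
            }
        return cls(**d)


@dataclass
class Cohort:
    """A synthetic cohort: episode-level summary plus a per-visit table.

    ``episodes`` carries one row per episode of care (demographics, centre,
    visit count and the hidden ``true_cluster`` label, retained solely for
    recovery testing); ``visits`` carries one row per visit with the
    clinical measures and flags the indicator mapping consumes.
    """

    episodes: pd.DataFrame
    visits: pd.DataFrame
    config: GeneratorConfig

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)


# ---------------------------------------------------------------------------
# Generation


def _draw_categorical(rng: np.random.Generator, levels: Sequence[str],
                      probs: Sequence[float], n: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ConfigurationError("categorical marginals must be a probability vector")
    return np.asarray(levels, dtype=object)[rng.choice(len(levels), size=n, p=p / p.sum())]


def _calibrate_intercepts(target: np.ndarray, tilt: np.ndarray) -> np.ndarray:
    """Fixed-point search for softmax intercepts whose cohort-average
    membership probabilities equal ``target`` given per-episode logit tilts."""
    alpha = np.log(np.clip(target, 1e-12, None))
    for _ in range(200):
        logits = alpha[None, :] + tilt
        logits -= logits.max(axis=1, keepdims=True)
        prob = np.exp(logits)
        prob /= prob.sum(axis=1, keepdims=True)
        marg = prob.mean(axis=0)
        step = np.log(np.clip(target, 1e-12, None)) - np.log(np.clip(marg, 1e-300, None))
        alpha += step
        if np.abs(step).max() < 1e-12:
            break
    return alpha


def _membership_probabilities(config: GeneratorConfig,
                              demographics: pd.DataFrame) -> np.ndarray:
    n, k = len(demographics), config.k
    tilt = np.zeros((n, k))
    for fname, levels in config.demographic_effects.items():
        col = demographics[fname].to_numpy()
        for level, vec in levels.items():
            tilt[col == level] += np.asarray(vec, dtype=float)
    alpha = _calibrate_intercepts(np.asarray(config.cluster_proportions, float), tilt)
    logits = alpha[None, :] + tilt
    logits -= logits.max(axis=1, keepdims=True)
    prob = np.exp(logits)
    prob /= prob.sum(axis=1, keepdims=True)
    return prob


def _sample_rows(rng: np.random.Generator, prob: np.ndarray) -> np.ndarray:
    """Draw one categorical outcome per row of a probability matrix."""
    u = rng.random(prob.shape[0])
    return (prob.cumsum(axis=1) < u[:, None]).sum(axis=1)


def _forced_any_fires(rng: np.random.Generator, state: np.ndarray,
                      n_visits: np.ndarray, visit_ep: np.ndarray,
                      per_visit_rate: float = 0.5) -> np.ndarray:
    """Per-visit fire pattern consistent with an episode-level binary state.

    State-0 episodes never fire; state-1 episodes fire at each visit with
    ``per_visit_rate`` but are guaranteed at least one firing visit, so
    any-visit aggregation reproduces the planted state exactly.
    """
    fires = (rng.random(len(visit_ep)) < per_visit_rate) & (state[visit_ep] == 1)
    n_fired = np.bincount(visit_ep, weights=fires, minlength=len(state))
    need = (state == 1) & (n_fired == 0)
    if need.any():
        first = np.concatenate([[0], np.cumsum(n_visits)[:-1]])
        pick = first[need] + rng.integers(0, n_visits[need])
        fires[pick] = True
    return fires


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a seeded synthetic cohort with planted cluster structure.

    Latent cluster membership is drawn from ``cluster_proportions`` tilted
    per episode by the demographic log-relative-risk effects (with
    intercepts calibrated so the marginal shares still match the configured
    proportions); binary indicator states follow the cluster's profile row;
    continuous measures are then sampled from the matching side of each
    indicator's cut-point so the downstream threshold mapping reproduces
    the planted states exactly.  Identical config (seed included) yields a
    byte-identical cohort.
    """
    config.validate()
    n, k = config.n_episodes, config.k
    if n < k:
        raise DegenerateSizeError(f"n_episodes={n} smaller than K={k}")
    rng = np.random.default_rng([config.seed, 0])

    # demographics from their marginals
    demo = {}
    for fname, levels in config.demographic_marginals.items():
        names = list(levels.keys())
        demo[fname] = _draw_categorical(rng, names, [levels[l] for l in names], n)
    demographics = pd.DataFrame(demo)

    # latent cluster membership
    prob = _membership_probabilities(config, demographics)
    cluster = _sample_rows(rng, prob)  # 0-based

    # centres: heterogeneous cluster mixes via a Dirichlet prior
    alpha = config.centre_mixing * np.clip(
        np.asarray(config.cluster_proportions), 1e-6, None
    )
    theta = rng.dirichlet(alpha, size=config.n_centres)  # n_centres x K
    centre_prob = theta / np.clip(theta.sum(axis=0, keepdims=True), 1e-300, None)
    centre = np.empty(n, dtype=int)
    for c in range(k):
        idx = np.flatnonzero(cluster == c)
        if len(idx) == 0:
            continue
        pc = np.ascontiguousarray(centre_prob[:, c], dtype=float)
        total = pc.sum()
        if total <= 0 or not np.isfinite(total):  # vanishing mixture component
            pc = np.full(config.n_centres, 1.0 / config.n_centres)
        else:
            pc /= total
        centre[idx] = rng.choice(config.n_centres, size=len(idx), p=pc)

    # visit counts: shifted negative binomial with cluster-specific mean
    rates = np.asarray(config.visit_rate_by_cluster, float)[cluster]
    mu = np.clip(rates - 1.0, 0.01, None)
    disp = config.visit_dispersion
    n_visits = 1 + rng.negative_binomial(disp, disp / (disp + mu))

    # planted indicator states: Gaussian-copula uniforms preserve the
    # profile marginals while adding within-cluster residual dependence
    profiles = config.profiles()
    n_ind = len(INDICATOR_NAMES)
    R = np.eye(n_ind)
    idx_of = {name: j for j, name in enumerate(INDICATOR_NAMES)}
    for block, rho in config.residual_blocks:
        ids = [idx_of[name] for name in block]
        for a in ids:
            for b in ids:
                if a != b:
                    R[a, b] = rho
    z = rng.standard_normal((n, n_ind)) @ np.linalg.cholesky(R).T
    u = stats.norm.cdf(z)
    states = (u < profiles[cluster]).astype(np.int8)

    # person / episode identifiers with a share of repeat clients
    episode_id = np.array([f"E{i:07d}" for i in range(n)], dtype=object)
    person_num = np.arange(n)
    repeats = rng.random(n) < config.repeat_person_fraction
    repeats[0] = False
    prior = rng.integers(0, np.maximum(np.arange(n), 1))
    person_num[repeats] = person_num[prior[repeats]]
    person_id = np.array([f"P{i:07d}" for i in person_num], dtype=object)

    episodes = pd.DataFrame(
        {
            "episode_id": episode_id,
            "person_id": person_id,
            "centre_id": np.array([f"C{i:03d}" for i in centre], dtype=object),
            **{f: demographics[f].to_numpy() for f in demographics.columns},
            "n_visits": n_visits.astype(int),
            "true_cluster": (cluster + 1).astype(int),
        }
    )

    # ------------------------------------------------------------------ visits
    visit_ep = np.repeat(np.arange(n), n_visits)
    nv_total = len(visit_ep)
    visit_number = np.concatenate([np.arange(1, v + 1) for v in n_visits])

    def scale_draw(state_col: np.ndarray, lo_true: int, hi_true: int,
                   lo_false: int, hi_false: int) -> np.ndarray:
        s = states[visit_ep, state_col]
        out = np.where(
            s == 1,
            rng.integers(lo_true, hi_true + 1, size=nv_total),
            rng.integers(lo_false, hi_false + 1, size=nv_total),
        )
        return out.astype(float)

    i = {name: j for j, name in enumerate(INDICATOR_NAMES)}
    k10 = scale_draw(i["distress"], 31, 50, 10, 30)
    mlt_cut = int(round(config.mlt_cut))
    mlt = scale_draw(i["low_qol"], 0, mlt_cut - 1, mlt_cut, 100)
    sofas = scale_draw(i["low_functioning"], 0, 60, 61, 100)

    stage_state = states[visit_ep, i["later_stage"]]
    stage = np.where(
        stage_state == 1,
        np.asarray(["2", "3", "4"], object)[rng.choice(3, size=nv_total, p=[0.6, 0.25, 0.15])],
        np.asarray(["1a", "1b"], object)[rng.choice(2, size=nv_total, p=[0.45, 0.55])],
    )

    sev_state = states[visit_ep, i["severe_disorder"]]
    diag = np.where(
        sev_state == 1,
        np.asarray(SEVERE_DIAGNOSES, object)[
            rng.choice(len(SEVERE_DIAGNOSES), size=nv_total, p=[0.35, 0.3, 0.25, 0.1])
        ],
        np.asarray(OTHER_DIAGNOSES, object)[
            rng.choice(len(OTHER_DIAGNOSES), size=nv_total, p=[0.4, 0.35, 0.1, 0.1, 0.05])
        ],
    )

    sh_fires = _forced_any_fires(rng, states[:, i["self_harm"]], n_visits, visit_ep)
    other_issue = np.asarray(PRESENTING_ISSUES[1:], object)[
        rng.choice(5, size=nv_total, p=[0.62, 0.08, 0.18, 0.08, 0.04])
    ]
    presenting = np.where(sh_fires, PRESENTING_ISSUES[0], other_issue)

    visits = pd.DataFrame(
        {
            "episode_id": episode_id[visit_ep],
            "visit_number": visit_number,
            "k10_total": k10,
            "sofas": sofas,
            "mlt_total": mlt,
            "stage": stage,
            "diagnosis_codes": diag,
            "presenting_issue": presenting,
        }
    )
    for flag, name in zip(
        FLAG_FIELDS,
        ("aod_treatment", "trauma", "housing", "neet", "eet_issue", "benefits", "cooccurring"),
    ):
        fires = _forced_any_fires(rng, states[:, i[name]], n_visits, visit_ep)
        visits[flag] = pd.array(fires, dtype="boolean")

    return Cohort(episodes=episodes, visits=visits, config=config)


# ---------------------------------------------------------------------------
# Missingness


def apply_missingness(cohort: Cohort, config: Optional[GeneratorConfig] = None) -> Cohort:
    """Blank indicator source fields according to the missingness design.

    An ``all_missing_fraction`` share of episodes loses every
    indicator-relevant field (the stratum excluded from analysis);
    remaining episode-item pairs are blanked independently at
    ``missing_rate_item`` — MCAR by default, or with missingness odds
    multiplied by ``mar_odds`` for episodes at ``mar_field == mar_level``
    (MAR).  Missingness is recorded as NA values in the visit table; no
    imputation happens here.
    """
    config = config or cohort.config
    for rate, name in (
        (config.missing_rate_item, "missing_rate_item"),
        (config.all_missing_fraction, "all_missing_fraction"),
    ):
        if not 0 <= rate < 1:
            raise ConfigurationError(f"{name} must lie in [0, 1), got {rate}")
    if config.missing_rate_item == 0 and config.all_missing_fraction == 0:
        return cohort

    rng = np.random.default_rng([config.seed, 1])
    episodes = cohort.episodes
    n = len(episodes)
    n_items = len(INDICATOR_NAMES)

    all_missing = rng.random(n) < config.all_missing_fraction

    rate = np.full(n, config.missing_rate_item)
    if config.mar_field is not None and config.missing_rate_item > 0:
        if config.mar_field not in episodes.columns:
            raise ConfigurationError(f"MAR field {config.mar_field!r} not in episode table")
        odds = rate / (1 - rate) * config.mar_odds
        tilted = odds / (1 + odds)
        sel = episodes[config.mar_field].to_numpy() == config.mar_level
        rate = np.where(sel, tilted, rate)

    item_missing = rng.random((n, n_items)) < rate[:, None]
    item_missing[all_missing] = True

    visits = cohort.visits.copy()
    ep_index = pd.Series(np.arange(n), index=episodes["episode_id"].to_numpy())
    visit_ep = ep_index[visits["episode_id"]].to_numpy()
    for j, fld in enumerate(INDICATOR_SOURCE_FIELDS):
        mask = item_missing[visit_ep, j]
        if visits[fld].dtype == object:
            col = visits[fld].copy()
            col[mask] = None
            visits[fld] = col
        elif str(visits[fld].dtype) == "boolean":
            col = visits[fld].copy()
            col[mask] = pd.NA
            visits[fld] = col
        else:
            visits[fld] = visits[fld].mask(mask, np.nan)

    return Cohort(episodes=episodes, visits=visits, config=config)


def with_overrides(config: GeneratorConfig, **kwargs) -> GeneratorConfig:
    """Return a copy of ``config`` with the given fields replaced."""
    return replace(config, **kwargs)
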
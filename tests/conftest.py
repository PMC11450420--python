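import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import careclust as cc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """Small default-condition cohort with item and all-missing missingness."""
    config = cc.GeneratorConfig(n_episodes=1500, seed=11)
    return cc.apply_missingness(cc.generate_cohort(config))


@pytest.fixture(scope="session")
def complete_cohort():
    """Default-condition cohort with no missingness (round-trip tests)."""
    config = cc.GeneratorConfig(
        n_episodes=1500, seed=12, missing_rate_item=0.0, all_missing_fraction=0.0
    )
    return cc.generate_cohort(config)


@pytest.fixture(scope="session")
def separable_imps():
    """Imputation set over a well-separated 4-profile cohort (no missingness:
    the completed copies are identical), plus the hidden labels."""
    config = cc.GeneratorConfig(
        n_episodes=1200,
        seed=13,
        indicator_profiles=cc.well_separated_profiles(4),
        missing_rate_item=0.0,
        all_missing_fraction=0.0,
    )
    cohort = cc.generate_cohort(config)
    mat = cc.derive_indicators(cohort)
    filtered, _ = cc.exclusion_filter(mat)
    imps = cc.impute(filtered, m_count=2, seed=99)
    truth = (
        cohort.episodes.set_index("episode_id")
        .loc[list(filtered.episode_ids)]["true_cluster"]
        .to_numpy()
    )
    return imps, truth, cohort
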
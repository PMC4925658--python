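import numpy as np
import pytest

from occmap import CohortConfig, EffectSpec, match_pairs, simulate_cohort
from occmap.dkt import DKT_REGIONS


@pytest.fixture(scope="session")
def small_null_cohort():
    """20 + 20 cohort with identical case/control feature distributions."""
    config = CohortConfig(n_cases=20, n_controls=20, seed=7)
    features, subjects = simulate_cohort(config, EffectSpec.null())
    return features, subjects, config


@pytest.fixture(scope="session")
def planted_cohort():
    """40 + 40 cohort with 10 planted features and heterogeneous controls."""
    planted = planted_features()
    sizes = planted_sizes()
    config = CohortConfig(n_cases=40, n_controls=40, seed=11)
    effects = EffectSpec(
        affected_features=planted, effect_sizes=sizes, control_heterogeneity=1.5
    )
    features, subjects = simulate_cohort(config, effects)
    return features, subjects, effects


@pytest.fixture(scope="session")
def matched_null(small_null_cohort):
    features, subjects, _ = small_null_cohort
    return features, subjects, match_pairs(subjects)


def planted_features():
    measures = ["Area", "Volume", "Thickness", "ThicknessStd", "MeanCurv"] * 2
    return [("lh", DKT_REGIONS[i], m) for i, m in zip(range(0, 20, 2), measures)]


def planted_sizes():
    return [1.5, -1.5, 1.5, 1.5, -1.5, 1.5, -1.5, 1.5, 1.5, -1.5]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
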
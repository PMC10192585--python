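import numpy as np
import pytest

from mirrorloop.montage import standard_montage
from mirrorloop.simulate import (ArtifactConfig, CohortSpec, ExecutionConfig,
                                 PassiveConfig, SpellerConfig, simulate_cohort)


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


def small_cohort_spec(n_subjects: int = 1, seed: int = 7, **effect_kw) -> CohortSpec:
    """A scaled-down cohort for unit tests: same structure, fewer trials."""
    spec = CohortSpec(
        n_subjects=n_subjects,
        seed=seed,
        speller=SpellerConfig(n_trials=10, n_forced_errors=4, reps_per_finger=5,
                              inter_trial_s=2.0),
        passive=PassiveConfig(n_actions=16),
        execution=ExecutionConfig(n_actions=8),
        artifacts=ArtifactConfig(enabled=False),
    )
    for key, value in effect_kw.items():
        setattr(spec.effects, key, value)
    return spec


@pytest.fixture(scope="session")
def small_subject():
    """One simulated subject of the scaled-down cohort (no artifacts)."""
    return simulate_cohort(small_cohort_spec())[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
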
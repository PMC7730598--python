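import numpy as np
import pytest

import kneeload as kl
from kneeload.preprocess import build_tensor, detect_stance, preprocess_trial


@pytest.fixture(scope="session")
def small_cfg():
    """A compact cohort configuration used across the unit tests."""
    return kl.CohortConfig(
        n_subjects=4, speed_grid=(3, 4), seconds_per_speed=6.0, master_seed=42
    )


@pytest.fixture(scope="session")
def small_profiles(small_cfg):
    return kl.make_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_trials(small_cfg, small_profiles):
    return kl.synthesize_cohort_trials(small_profiles, small_cfg)


@pytest.fixture(scope="session")
def small_tensor(small_trials):
    tensor, _ = build_tensor(small_trials)
    return tensor


@pytest.fixture(scope="session")
def one_trial(small_cfg, small_profiles):
    return kl.synthesize_trial(small_profiles[0], "right", 3, small_cfg)


@pytest.fixture(scope="session")
def one_processed(one_trial):
    kcf = kl.attach_ground_truth(one_trial)
    return preprocess_trial(one_trial, kcf)


@pytest.fixture(scope="session")
def one_stances(one_processed):
    return detect_stance(one_processed)
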
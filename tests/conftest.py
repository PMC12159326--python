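import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from deprisk.phenotypes import apply_exclusion_cascade, code_cohort
from deprisk.synthetic import SyntheticConfig, default_true_model, simulate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth_model():
    return default_true_model()


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_participants=4000, n_families=3800, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def small_analytic(small_cohort):
    coded = code_cohort(small_cohort)
    analytic, _ = apply_exclusion_cascade(coded, seed=11, reporter="youth")
    return analytic


def make_profile(**overrides) -> dict:
    """All-reference predictor profile with optional overrides."""
    profile = {
        "sex_female": 0,
        "nonwhite": 0,
        "trauma": 0,
        "school_disengaged": 0,
        "loneliness": 0,
        "fights": 0,
        "ran_away": 0,
        "substance_ever": 0,
        "caregiver1_q": 1,
        "caregiver2_q": 1,
        "family_conflict_q": 1,
    }
    profile.update(overrides)
    return profile


def profile_frame(profiles) -> pd.DataFrame:
    df = pd.DataFrame(list(profiles))
    df.insert(0, "participant_id", [f"T{i:04d}" for i in range(len(df))])
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
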
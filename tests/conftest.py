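import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from epsm.features import extract_feature_matrix
from epsm.preprocessing import preprocess_recording
from epsm.synthetic import (
    PopulationSpec,
    default_activities,
    generate_dataset,
)

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def small_activities():
    """Four activities (two static postures, two motions) — enough to
    exercise baseline weighting and frequency features while staying fast."""
    acts = {a.name: a for a in default_activities()}
    return [acts["standing"], acts["sitting"], acts["walking"],
            acts["running"]]


@pytest.fixture(scope="session")
def small_spec():
    return PopulationSpec(
        n_users=4, activities=small_activities(), fs=50.0,
        trials_per_activity=2, trial_duration=15.0, inter_trial_gap=2.0,
        noise_sd=0.3, hetero_sd=0.5, seed=7)


@pytest.fixture(scope="session")
def small_recordings(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def small_trials(small_recordings):
    trials = []
    for rec in small_recordings:
        trials.extend(preprocess_recording(rec))
    return trials


@pytest.fixture(scope="session")
def small_matrix(small_trials):
    """4 users x 4 activities x 2 trials x 9 windows = 288 rows."""
    return extract_feature_matrix(small_trials)


def random_grouped_matrix(rng, n_users=3, n_labels=2, trials_per=3,
                          rows_per_trial=4):
    """A random feature-matrix-shaped frame with trial/user/label metadata,
    for split-protocol property tests."""
    rows = []
    for u in range(n_users):
        for lab in range(n_labels):
            for t in range(trials_per):
                tid = f"u{u}|t{lab}_{t}"
                for _ in range(rows_per_trial):
                    rows.append({
                        "user": f"u{u}", "trial": tid, "label": f"a{lab}",
                        "f0": rng.normal(), "f1": rng.normal()})
    frame = pd.DataFrame(rows)
    return frame.sample(frac=1.0, random_state=int(rng.integers(2**31))
                        ).reset_index(drop=True)
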
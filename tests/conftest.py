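import numpy as np
import pytest

from emodecode import (CVConfig, Montage, decode_cohort, default_montage,
                       reduced_study_config)
from emodecode.features import FeatureArray, FeatureDescriptor


@pytest.fixture(scope="session")
def montage63() -> Montage:
    return default_montage()


@pytest.fixture(scope="session")
def toy_montage() -> Montage:
    """One frontal pair plus one midline channel."""
    return Montage(
        channel_names=("F3", "F4", "Cz"),
        region={"F3": "frontal", "F4": "frontal", "Cz": "midline"},
        hemisphere={"F3": "left", "F4": "right", "Cz": "midline"},
        homologous_pairs=(("F3", "F4"),),
    )


def make_blob_features(n_trials: int = 20, windows_per_trial: int = 6,
                       n_features: int = 24, shift: float = 2.0,
                       seed: int = 0, participant_id: int = 0) -> FeatureArray:
    """Trial-structured Gaussian features with a class mean shift on the
    first half of the columns; used by classifier/visualization tests."""
    rng = np.random.default_rng(seed)
    labels_t = np.repeat([0, 1], n_trials // 2)
    X, labels, groups = [], [], []
    for t in range(n_trials):
        mu = np.zeros(n_features)
        mu[: n_features // 2] = shift * (1 if labels_t[t] else -1)
        X.append(rng.normal(mu, 1.0, size=(windows_per_trial, n_features)))
        labels.extend([labels_t[t]] * windows_per_trial)
        groups.extend([t] * windows_per_trial)
    desc = tuple(FeatureDescriptor("band_power", "alpha", channel=f"ch{i}")
                 for i in range(n_features))
    return FeatureArray(np.vstack(X), desc, np.array(labels), np.array(groups),
                        participant_id)


@pytest.fixture(scope="session")
def blob_features() -> FeatureArray:
    return make_blob_features()


# Shared simulated-cohort decodings (reduced problem size: 2 blocks per
# condition, 6-s segments -> 16 trials / 96 windows per participant).

@pytest.fixture(scope="session")
def cohort_delta15():
    cfg = reduced_study_config(seed=2301, faa_effect=1.5)
    return decode_cohort(cfg, CVConfig(seed=97))


@pytest.fixture(scope="session")
def cohort_delta0():
    cfg = reduced_study_config(seed=2302, faa_effect=0.0)
    return decode_cohort(cfg, CVConfig(seed=98))
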
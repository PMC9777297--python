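"""End-to-end drivers: simulate -> preprocess -> features -> decode.

These are the entry points the analysis scripts and the acceptance checks
run; each step delegates to the corresponding module.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bands import ALPHA
from .classification import CVConfig, CVResult, permutation_baseline, run_cv
from .correlation import extract_correlation_features
from .features import FeatureArray
from .preprocessing import epoch_windows, remove_artifacts_ica
from .selection import RankedFeatures, rank_features
from .synthetic import Recording, SimConfig, generate_cohort
from .timefreq import extract_timefreq_features


def reduced_study_config(seed: int, faa_effect: float = 1.0,
                         n_participants: int = 14) -> SimConfig:
    """The study design at the reduced problem size used for desk-scale runs.

    The trial structure (alternating pleasure/grief blocks of four emotion
    segments with interleaved neutral segments) is preserved; block count and
    segment length are halved relative to the full design (2 blocks per
    condition, 6-s segments -> 16 trials, 96 labeled windows per participant)
    and artifacts are disabled so runs need no ICA pass.
    """
    return SimConfig(n_participants=n_participants, blocks_per_condition=2,
                     segment_duration=6.0, artifact_rate=0.0,
                     faa_effect=faa_effect, seed=seed)


def extract_features(recording: Recording, feature_set: str = "timefreq_faa",
                     clean: bool = False, window_s: float = 1.0) -> FeatureArray:
    """Window one recording and extract the requested feature set."""
    if clean:
        recording = remove_artifacts_ica(recording)
    windows = epoch_windows(recording, window_s=window_s)
    if feature_set == "timefreq_faa":
        return extract_timefreq_features(windows, montage=recording.montage)
    if feature_set == "correlation":
        return extract_correlation_features(windows, montage=recording.montage)
    raise ValueError(f"unknown feature set {feature_set!r}")


@dataclass(frozen=True)
class CohortDecoding:
    """Per-participant decoding results over one simulated cohort."""

    results: tuple[CVResult, ...]
    rankings: tuple[RankedFeatures, ...]
    features: tuple[FeatureArray, ...]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.mean for r in self.results]))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant": [r.participant_id for r in self.results],
            "mean_accuracy": [r.mean for r in self.results],
            "sd_accuracy": [r.sd for r in self.results],
            "feature_set": [r.feature_set for r in self.results],
        })


def decode_cohort(sim_config: SimConfig, cv_config: CVConfig = CVConfig(),
                  feature_set: str = "timefreq_faa",
                  clean: bool | None = None) -> CohortDecoding:
    """Simulate a cohort and run trial-grouped CV per participant.

    Also fits one whole-session feature ranking per participant (used for the
    cross-participant top-feature pooling; fold-wise rankings used inside the
    classifier are refit per training fold and are separate from this).
    """
    if clean is None:
        clean = sim_config.artifact_rate > 0
    results, rankings, feats = [], [], []
    for recording in generate_cohort(sim_config):
        fa = extract_features(recording, feature_set=feature_set, clean=clean)
        cv = replace(cv_config, seed=cv_config.seed + 131 * recording.participant_id)
        results.append(run_cv(fa, cv, feature_set=feature_set))
        rankings.append(rank_features(fa.X, fa.labels, method=cv_config.ranking))
        feats.append(fa)
    return CohortDecoding(tuple(results), tuple(rankings), tuple(feats))


def cohort_permutation_pvalues(decoding: CohortDecoding,
                               cv_config: CVConfig = CVConfig(),
                               n_perm: int = 99) -> pd.DataFrame:
    """Trial-permutation p-value per participant of a decoded cohort."""
    rows = []
    for fa in decoding.features:
        cv = replace(cv_config, seed=cv_config.seed + 131 * fa.participant_id)
        observed, _, p = permutation_baseline(fa, cv, n_perm=n_perm)
        rows.append((fa.participant_id, observed, p))
    return pd.DataFrame(rows, columns=["participant", "accuracy", "p_value"])


def faa_contrast(features: FeatureArray, band_name: str = ALPHA.name) -> float:
    """Mean FAA difference (pleasure minus grief windows) over FAA columns.

    On synthetic data this recovers the injected asymmetry contrast delta.
    """
    faa_cols = [i for i, d in enumerate(features.descriptors)
                if d.feature_type == "faa" and d.band == band_name]
    if not faa_cols:
        raise ValueError("feature array has no FAA columns")
    X = features.X[:, faa_cols]
    pleasure = X[features.labels == 1].mean()
    grief = X[features.labels == 0].mean()
    return float(pleasure - grief)
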
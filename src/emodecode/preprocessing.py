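"""Continuous-EEG cleaning and epoching into labeled 1-s windows.

The pipeline keeps every window (no epoch rejection); artifact handling is
done once on the continuous signal by zeroing ICA components that track a
frontal low-frequency blink reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA

from .synthetic import Recording

LABEL_BY_CONDITION = {"pleasure": 1, "grief": 0}


@dataclass(frozen=True)
class WindowSet:
    """Labeled fixed-length windows cut from emotion segments.

    ``windows`` is (n_windows, n_channels, window_samples); ``labels`` is 1
    for pleasure and 0 for grief; ``groups`` carries the trial id so that a
    grouped cross-validation can keep all windows of one trial in one fold.
    Neutral segments never contribute labeled windows.
    """

    windows: np.ndarray
    labels: np.ndarray
    groups: np.ndarray
    participant_id: int
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.windows.ndim != 3:
            raise ValueError("windows must be (n_windows, n_channels, n_samples)")
        n = self.windows.shape[0]
        if not (len(self.labels) == len(self.groups) == n):
            raise ValueError("labels/groups length mismatch")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


def save_window_set(window_set: WindowSet, path) -> None:
    """Persist windows as a compressed array container plus a CSV index
    of (window_id, trial_id, label) next to it."""
    from pathlib import Path
    path = Path(path)
    np.savez_compressed(path, windows=window_set.windows,
                        labels=window_set.labels, groups=window_set.groups,
                        participant_id=window_set.participant_id,
                        sampling_rate=window_set.sampling_rate)
    lines = ["window_id,trial_id,label"] + [
        f"{i},{g},{l}" for i, (g, l) in
        enumerate(zip(window_set.groups, window_set.labels))]
    path.with_suffix(".csv").write_text("\n".join(lines) + "\n")


def load_window_set(path) -> WindowSet:
    with np.load(path) as z:
        return WindowSet(windows=z["windows"], labels=z["labels"],
                         groups=z["groups"],
                         participant_id=int(z["participant_id"]),
                         sampling_rate=float(z["sampling_rate"]))


def bandpass_filter(recording: Recording, f_lo: float, f_hi: float,
                    order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward), length preserved."""
    nyq = recording.sampling_rate / 2.0
    if not 0 < f_lo < f_hi < nyq:
        raise ValueError(f"invalid band ({f_lo}, {f_hi}) for fs={recording.sampling_rate}")
    sos = signal.butter(order, [f_lo, f_hi], btype="bandpass",
                        fs=recording.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1)
    return replace(recording, data=filtered)


def _blink_reference(recording: Recording) -> np.ndarray:
    """Mean of the two fronto-polar channels, low-passed to the 1-4 Hz range."""
    montage = recording.montage
    idx = [montage.index(c) for c in ("Fp1", "Fp2") if c in montage.channel_names]
    if not idx:
        raise ValueError("montage lacks fronto-polar channels for blink reference")
    ref = recording.data[idx].mean(axis=0)
    sos = signal.butter(4, [1.0, 4.0], btype="bandpass",
                        fs=recording.sampling_rate, output="sos")
    return signal.sosfiltfilt(sos, ref)


def remove_artifacts_ica(recording: Recording, n_components: int | None = None,
                         threshold: float = 0.7, seed: int = 0,
                         max_iter: int = 500) -> Recording:
    """Zero ICA components correlated with the frontal blink reference.

    The recording is decomposed with FastICA; any component whose absolute
    Pearson correlation with the 1-4 Hz fronto-polar reference exceeds
    ``threshold`` is zeroed before reconstruction.  With ``threshold`` above
    1 no component can qualify and the signal is returned unchanged.
    """
    n_ch = recording.data.shape[0]
    if n_components is None:
        n_components = min(n_ch, 32)
    if n_components > n_ch:
        raise ValueError("n_components exceeds channel count")
    if threshold > 1.0:
        return recording

    reference = _blink_reference(recording)
    X = recording.data.T  # samples x channels
    mean = X.mean(axis=0)
    ica = FastICA(n_components=n_components, random_state=seed,
                  max_iter=max_iter, whiten="unit-variance", tol=1e-3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warning re-raised below
        sources = ica.fit_transform(X - mean)
    if not np.all(np.isfinite(ica.components_)):
        raise RuntimeError(
            f"FastICA diverged (non-finite unmixing matrix) with "
            f"n_components={n_components}, max_iter={max_iter}")
    if ica.n_iter_ >= max_iter:
        # The tolerance criterion tracks *all* unmixing vectors; on EEG whose
        # background is near-Gaussian the noise subspace rotates freely and
        # the criterion is rarely met, while the artifact component itself
        # stabilises within a few iterations.  So this is a warning, not an
        # error.
        warnings.warn(f"FastICA stopped at max_iter={max_iter} without meeting "
                      "its tolerance; artifact components are typically still "
                      "recovered")

    ref = (reference - reference.mean()) / reference.std()
    # compare like with like: restrict sources to the same 1-4 Hz band the
    # reference lives in before correlating
    sos = signal.butter(4, [1.0, 4.0], btype="bandpass",
                        fs=recording.sampling_rate, output="sos")
    low = signal.sosfiltfilt(sos, sources, axis=0)
    sd = low.std(axis=0)
    src = (low - low.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    corr = np.abs(src.T @ ref) / len(ref)
    removed = corr > threshold
    # subtract only the flagged components' contribution; the residual
    # outside the ICA subspace is untouched
    artifact = sources[:, removed] @ ica.mixing_[:, removed].T
    return replace(recording, data=(X - artifact).T)


def epoch_windows(recording: Recording, window_s: float = 1.0) -> WindowSet:
    """Cut each emotion segment into non-overlapping labeled windows.

    A 12-s segment yields 12 one-second windows, all sharing the segment's
    trial id as their group.  Segments shorter than one window are skipped
    with a warning; neutral segments are ignored.
    """
    fs = recording.sampling_rate
    win = round(window_s * fs)
    windows, labels, groups = [], [], []
    for a in recording.annotations:
        if a.condition not in LABEL_BY_CONDITION:
            continue
        n_fit = int(a.duration * fs) // win
        if n_fit == 0:
            warnings.warn(f"trial {a.trial_id}: segment shorter than window, skipped")
            continue
        start = round(a.onset * fs)
        for w in range(n_fit):
            windows.append(recording.data[:, start + w * win:start + (w + 1) * win])
            labels.append(LABEL_BY_CONDITION[a.condition])
            groups.append(a.trial_id)
    if windows:
        arr = np.stack(windows)
    else:
        arr = np.empty((0, recording.data.shape[0], win))
    return WindowSet(windows=arr, labels=np.asarray(labels, dtype=int),
                     groups=np.asarray(groups, dtype=int),
                     participant_id=recording.participant_id, sampling_rate=fs)
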
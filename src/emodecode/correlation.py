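"""Amplitude-envelope Spearman correlation features.

For each 1-s window and each frequency band, every channel is band-pass
filtered, its amplitude envelope taken as the magnitude of the analytic
signal (Hilbert transform), and the channels' envelopes are correlated with
Spearman's rank correlation.  The strict upper triangle of each band's
n x n correlation matrix, concatenated over bands in a fixed order, is the
feature row: with 63 channels and seven bands, 63*62/2 * 7 = 13,671 features.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal
from scipy.stats import rankdata

from .bands import CORRELATION_BANDS, BandSpec
from .features import FeatureArray, FeatureDescriptor, flag_zero_variance
from .montage import Montage
from .preprocessing import WindowSet


def band_envelope(window: np.ndarray, band: BandSpec,
                  sampling_rate: float = 250.0, order: int = 4) -> np.ndarray:
    """Amplitude envelope per channel: band-pass then |analytic signal|."""
    nyq = sampling_rate / 2.0
    if not 0 < band.f_lo < band.f_hi < nyq:
        raise ValueError(f"band ({band.f_lo}, {band.f_hi}) invalid for fs={sampling_rate}")
    x = np.atleast_2d(window)
    sos = signal.butter(order, [band.f_lo, band.f_hi], btype="bandpass",
                        fs=sampling_rate, output="sos")
    narrow = signal.sosfiltfilt(sos, x, axis=-1)
    env = np.abs(signal.hilbert(narrow, axis=-1))
    return env.reshape(window.shape)


def spearman_matrix(envelopes: np.ndarray) -> np.ndarray:
    """Spearman correlation between channels (rows) of an envelope block.

    Each row is rank-transformed (average ranks on ties) and the Pearson
    correlation of the ranks is returned: symmetric with unit diagonal.
    A zero-variance row cannot be ranked meaningfully; its off-diagonal
    correlations are defined as 0 and a warning is emitted.
    """
    env = np.atleast_2d(envelopes)
    n_ch, n_s = env.shape
    if n_s < 3:
        raise ValueError("need at least 3 samples per channel")
    ranks = rankdata(env, axis=1)
    sd = ranks.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance channel(s): "
                      "correlations with them set to 0")
        ranks = ranks.copy()
        # give flat rows unit variance so corrcoef stays finite; zero after
        ranks[degenerate] = np.arange(n_s)
    corr = np.corrcoef(ranks)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def vectorize_upper(matrices: dict[str, np.ndarray] | list[np.ndarray]) -> np.ndarray:
    """Concatenate strict upper triangles of per-band square matrices.

    Band order follows the input order (dict insertion order or list order);
    within a band, pairs are taken row-major: (0,1), (0,2), ..., (n-2,n-1).
    """
    mats = list(matrices.values()) if isinstance(matrices, dict) else list(matrices)
    rows: list[np.ndarray] = []
    for m in mats:
        m = np.asarray(m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("correlation matrices must be square")
        iu = np.triu_indices(m.shape[0], k=1)
        rows.append(m[iu])
    return np.concatenate(rows) if rows else np.empty(0)


def upper_to_symmetric(vector: np.ndarray, n: int) -> np.ndarray:
    """Rebuild a symmetric unit-diagonal matrix from its strict upper triangle."""
    if len(vector) != n * (n - 1) // 2:
        raise ValueError("vector length does not match n(n-1)/2")
    out = np.eye(n)
    iu = np.triu_indices(n, k=1)
    out[iu] = vector
    out[(iu[1], iu[0])] = vector
    return out


def extract_correlation_features(window_set: WindowSet,
                                 bands: tuple[BandSpec, ...] = CORRELATION_BANDS,
                                 montage: Montage | None = None) -> FeatureArray:
    """Envelope-correlation feature rows for every window.

    Descriptors carry the channel pair and band of each column, in the same
    order as :func:`vectorize_upper` emits them.
    """
    if montage is None:
        raise ValueError("montage is required to name channel pairs")
    n_ch = montage.n_channels
    if window_set.n_windows == 0:
        return FeatureArray(np.empty((0, 0)), (), window_set.labels,
                            window_set.groups, window_set.participant_id)
    if window_set.windows.shape[1] != n_ch:
        raise ValueError("window channel count does not match montage")

    iu = np.triu_indices(n_ch, k=1)
    descriptors: list[FeatureDescriptor] = []
    for band in bands:
        for i, j in zip(*iu):
            pair = (montage.channel_names[i], montage.channel_names[j])
            descriptors.append(FeatureDescriptor("corr", band.name, pair=pair))

    fs = window_set.sampling_rate
    n_pairs = len(iu[0])
    X = np.empty((window_set.n_windows, n_pairs * len(bands)))
    for w in range(window_set.n_windows):
        parts = []
        for band in bands:
            env = band_envelope(window_set.windows[w], band, fs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                parts.append(spearman_matrix(env))
        X[w] = vectorize_upper(parts)
    desc = flag_zero_variance(tuple(descriptors), X)
    return FeatureArray(X, desc, window_set.labels, window_set.groups,
                        window_set.participant_id)
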
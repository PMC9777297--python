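"""Univariate feature ranking and top-k selection.

The primary criterion is a distance-discriminant score: for each feature
column, the absolute difference of the two class means standardised by the
root of the summed class variances,

    score_j = |mu_1j - mu_0j| / sqrt(var_1j + var_0j).

Two alternative backends sit behind the same interface: a greedy
maximum-relevance / minimum-redundancy (mRMR) ranking and a two-sample
Welch t-statistic ranking.  Selection is always fitted inside a training
fold; it never sees test rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureDescriptor
from .montage import Montage

RANKING_BACKENDS = ("fsdd", "mrmr", "ttest")


@dataclass(frozen=True)
class RankedFeatures:
    """Feature columns ordered by decreasing discriminant score."""

    indices: np.ndarray
    scores: np.ndarray
    k: int = 100

    def __post_init__(self) -> None:
        if len(self.indices) != len(self.scores):
            raise ValueError("indices and scores must align")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing along indices")

    @property
    def n_features(self) -> int:
        return len(self.indices)

    def to_frame(self, descriptors: Sequence[FeatureDescriptor] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"rank": np.arange(len(self.indices)),
                           "column": self.indices, "score": self.scores})
        if descriptors is not None:
            df["descriptor"] = [descriptors[i].label for i in self.indices]
        return df


def _class_split(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {len(classes)}")
    a, b = (X[y == c] for c in classes)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 samples")
    return a, b


def fsdd_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Standardised between-class mean distance per feature column."""
    a, b = _class_split(np.asarray(X, dtype=float), np.asarray(y))
    diff = np.abs(a.mean(axis=0) - b.mean(axis=0))
    denom = np.sqrt(a.var(axis=0, ddof=1) + b.var(axis=0, ddof=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = diff / denom
    scores[(diff == 0) & (denom == 0)] = 0.0
    return scores


def ttest_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Welch t| per feature column."""
    a, b = _class_split(np.asarray(X, dtype=float), np.asarray(y))
    t, _ = stats.ttest_ind(a, b, axis=0, equal_var=False)
    return np.abs(np.nan_to_num(t))


def _order_by_score(scores: np.ndarray) -> np.ndarray:
    # stable argsort on -scores: ties broken by ascending column index
    return np.argsort(-scores, kind="stable")


def mrmr_rank(X: np.ndarray, y: np.ndarray, max_greedy: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Greedy mRMR: relevance (distance-discriminant) minus mean |corr| with
    already-selected columns.  Greedy selection runs for the first
    ``max_greedy`` positions; the tail is appended in relevance order."""
    X = np.asarray(X, dtype=float)
    rel = fsdd_scores(X, y)
    n = X.shape[1]
    m = min(max_greedy, n)
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    selected: list[int] = []
    obj: list[float] = []
    red_sum = np.zeros(n)
    remaining = np.ones(n, dtype=bool)
    for step in range(m):
        if step == 0:
            crit = rel.copy()
        else:
            crit = rel - red_sum / step
        crit_masked = np.where(remaining, crit, -np.inf)
        j = int(np.argmax(crit_masked))
        selected.append(j)
        obj.append(float(crit_masked[j]))
        remaining[j] = False
        corr_j = np.abs(Z.T @ Z[:, j]) / X.shape[0]
        red_sum += np.where(remaining, corr_j, 0.0)
    tail = [int(j) for j in _order_by_score(rel) if remaining[j]]
    indices = np.array(selected + tail, dtype=int)
    # report a non-increasing score vector: greedy objective then tail relevance,
    # monotonised so the RankedFeatures ordering invariant holds
    raw = np.array(obj + [rel[j] for j in tail])
    scores = np.minimum.accumulate(raw)
    return indices, scores


def rank_features(X: np.ndarray, y: np.ndarray, method: str = "fsdd",
                  k: int = 100) -> RankedFeatures:
    """Rank all columns with the chosen backend."""
    if method not in RANKING_BACKENDS:
        raise ValueError(f"unknown ranking backend {method!r}")
    if method == "mrmr":
        indices, ordered = mrmr_rank(X, y)
    else:
        scores = fsdd_scores(X, y) if method == "fsdd" else ttest_scores(X, y)
        indices = _order_by_score(scores)
        ordered = scores[indices]
    return RankedFeatures(indices=indices, scores=ordered,
                          k=min(k, len(indices)))


def select_top_k(ranked: RankedFeatures, k: int | None = None) -> np.ndarray:
    """First k ranked column indices (ties already broken by column index)."""
    if k is None:
        k = ranked.k
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > ranked.n_features:
        raise ValueError(f"k={k} exceeds {ranked.n_features} features")
    return ranked.indices[:k]


def pool_top_features(per_participant_rankings: Sequence[RankedFeatures],
                      descriptors: Sequence[FeatureDescriptor],
                      top_n: int = 20) -> list[FeatureDescriptor]:
    """Concatenate every participant's top-n feature descriptors.

    Repetition is kept: 14 participants x top 20 gives a pool of 280
    elements whose regional/hemispheric composition is then tallied with
    :func:`topography_tally`.
    """
    pooled: list[FeatureDescriptor] = []
    for ranked in per_participant_rankings:
        for idx in select_top_k(ranked, min(top_n, ranked.n_features)):
            pooled.append(descriptors[idx])
    return pooled


def topography_tally(pooled: Sequence[FeatureDescriptor],
                     montage: Montage) -> pd.DataFrame:
    """Counts of pooled single-channel features per (region, hemisphere, band).

    Pair-valued features (FAA, correlations) have no single scalp site and
    are excluded from the channel tally; count them separately if needed.
    """
    rows = []
    for d in pooled:
        if d.channel is None:
            continue
        if d.channel not in montage.channel_names:
            raise ValueError(f"descriptor channel {d.channel!r} not in montage")
        rows.append((montage.region[d.channel], montage.hemisphere[d.channel],
                     d.band))
    if not rows:
        return pd.DataFrame(columns=["region", "hemisphere", "band", "count"])
    df = pd.DataFrame(rows, columns=["region", "hemisphere", "band"])
    return (df.value_counts(["region", "hemisphere", "band"])
              .rename("count").reset_index())
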
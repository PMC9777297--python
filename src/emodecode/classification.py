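"""Trial-grouped repeated k-fold SVM classification of 1-s windows.

Windows from one trial are strongly dependent, so folds are assigned at the
trial level: trials are shuffled and dealt round-robin to folds separately
per class (keeping folds class-balanced), and every window inherits its
trial's fold.  Standardisation and feature ranking are refit on the training
rows of each fold and only then applied to the test rows, so no test
information leaks into selection or scaling.  A trial-level label
permutation provides the chance baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureArray
from .selection import RankedFeatures, rank_features, select_top_k


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 5
    n_repeats: int = 10
    kernel: str = "linear"
    C: float = 1.0
    k_features: int | str = 100   # an int or "all"
    ranking: str = "fsdd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if isinstance(self.k_features, str) and self.k_features != "all":
            raise ValueError("k_features must be an int or 'all'")


@dataclass(frozen=True)
class CVResult:
    """Per-(repeat, fold) test accuracies plus recomputable summaries."""

    accuracies: pd.DataFrame  # columns: repeat, fold, accuracy
    participant_id: int
    feature_set: str = "timefreq_faa"

    @property
    def mean(self) -> float:
        return float(self.accuracies["accuracy"].mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies["accuracy"].std(ddof=1))

    def repeat_means(self) -> pd.Series:
        return self.accuracies.groupby("repeat")["accuracy"].mean()


def grouped_folds(groups: np.ndarray, n_folds: int, seed: int,
                  labels: np.ndarray | None = None) -> np.ndarray:
    """Fold index per window, assigned at the trial (group) level.

    Groups are shuffled deterministically and dealt round-robin to folds,
    class by class when labels are given, so each fold receives a balanced
    share of each class's trials.  Every window of a group lands in the
    group's fold.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < n_folds:
        raise ValueError(f"{len(uniq)} trial groups < {n_folds} folds")
    rng = np.random.default_rng(seed)
    if labels is None:
        group_label = {g: 0 for g in uniq}
    else:
        labels = np.asarray(labels)
        group_label = {}
        for g in uniq:
            lab = np.unique(labels[groups == g])
            if len(lab) != 1:
                raise ValueError(f"group {g} has mixed labels")
            group_label[g] = lab[0]
    fold_of_group: dict = {}
    slot = 0
    for cls in sorted(set(group_label.values())):
        cls_groups = np.array([g for g in uniq if group_label[g] == cls])
        rng.shuffle(cls_groups)
        for g in cls_groups:
            fold_of_group[g] = slot % n_folds
            slot += 1
    return np.array([fold_of_group[g] for g in groups])


def prepare_fold(X: np.ndarray, y: np.ndarray, train_idx: np.ndarray,
                 ranking: str = "fsdd") -> tuple[StandardScaler, RankedFeatures]:
    """Fit the scaler and feature ranking on training rows only."""
    scaler = StandardScaler().fit(X[train_idx])
    ranked = rank_features(scaler.transform(X[train_idx]), y[train_idx],
                           method=ranking)
    return scaler, ranked


def run_cv(features: FeatureArray, config: CVConfig = CVConfig(),
           feature_set: str = "timefreq_faa") -> CVResult:
    """Repeated trial-grouped k-fold SVM accuracy for one participant."""
    X, y, groups = features.X, features.labels, features.groups
    if isinstance(config.k_features, str):
        k = X.shape[1]
    else:
        k = min(config.k_features, X.shape[1])
    records = []
    for repeat in range(config.n_repeats):
        folds = grouped_folds(groups, config.n_folds,
                              seed=config.seed + repeat, labels=y)
        for fold in range(config.n_folds):
            test = folds == fold
            train = ~test
            if len(np.unique(y[train])) < 2:
                warnings.warn(f"repeat {repeat} fold {fold}: single-class "
                              "training set, fold skipped")
                continue
            scaler, ranked = prepare_fold(X, y, np.flatnonzero(train),
                                          ranking=config.ranking)
            cols = select_top_k(ranked, k)
            Xtr = scaler.transform(X[train])[:, cols]
            Xte = scaler.transform(X[test])[:, cols]
            clf = SVC(kernel=config.kernel, C=config.C)
            clf.fit(Xtr, y[train])
            acc = float(np.mean(clf.predict(Xte) == y[test]))
            records.append((repeat, fold, acc))
    df = pd.DataFrame(records, columns=["repeat", "fold", "accuracy"])
    return CVResult(accuracies=df, participant_id=features.participant_id,
                    feature_set=feature_set)


def permute_group_labels(labels: np.ndarray, groups: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Permute labels at the trial level (all windows of a trial together)."""
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    group_label = np.array([labels[groups == g][0] for g in uniq])
    permuted = rng.permutation(group_label)
    lut = dict(zip(uniq, permuted))
    return np.array([lut[g] for g in groups])


def permutation_baseline(features: FeatureArray, config: CVConfig = CVConfig(),
                         n_perm: int = 99, seed: int | None = None
                         ) -> tuple[float, np.ndarray, float]:
    """Trial-permutation null distribution and empirical p-value.

    Returns (observed mean accuracy, null accuracies, p) with
    p = (1 + #{null >= observed}) / (1 + n_perm).  Null runs use a single
    repeat per permutation; the observed statistic uses the full config.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = run_cv(features, config).mean
    rng = np.random.default_rng(config.seed + 7919 if seed is None else seed)
    null_cfg = replace(config, n_repeats=1)
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm_labels = permute_group_labels(features.labels, features.groups, rng)
        perm_features = FeatureArray(features.X, features.descriptors,
                                     perm_labels, features.groups,
                                     features.participant_id)
        null[p] = run_cv(perm_features,
                         replace(null_cfg, seed=config.seed + 1000 + p)).mean
    pval = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return observed, null, float(pval)
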
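"""UMAP feature-space embedding and top-feature topography plots."""

from __future__ import annotations

from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .features import FeatureArray, FeatureDescriptor
from .montage import Montage
from .selection import topography_tally


def embed_umap(features: FeatureArray | np.ndarray, n_neighbors: int = 15,
               min_dist: float = 0.1, seed: int = 0) -> np.ndarray:
    """2-D UMAP embedding of the window-feature rows (read-only stage)."""
    import umap  # deferred: numba JIT import is slow

    X = features.X if isinstance(features, FeatureArray) else np.asarray(features)
    if X.shape[0] < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} rows, "
                         f"got {X.shape[0]}")
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    return np.asarray(reducer.fit_transform(X))


def plot_embedding(coords: np.ndarray, labels: np.ndarray,
                   path: str | None = None) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab, name, color in ((1, "pleasure", "tab:orange"), (0, "grief", "tab:purple")):
        m = labels == lab
        ax.scatter(coords[m, 0], coords[m, 1], s=8, alpha=0.7,
                   label=name, color=color)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


def frontal_lr_ratio(tally: pd.DataFrame) -> tuple[int, int]:
    """(left, right) counts of frontal single-channel features in a tally."""
    frontal = tally[tally["region"] == "frontal"]
    left = int(frontal.loc[frontal["hemisphere"] == "left", "count"].sum())
    right = int(frontal.loc[frontal["hemisphere"] == "right", "count"].sum())
    return left, right


def plot_feature_topography(pooled: Sequence[FeatureDescriptor], montage: Montage,
                            path: str | None = None
                            ) -> tuple[plt.Figure, pd.DataFrame]:
    """Bar chart + tally table of pooled top features per region/hemisphere.

    Pair-valued descriptors (FAA, correlation) carry no single scalp site and
    are excluded from the tally; the left:right frontal count ratio is
    annotated on the figure.
    """
    tally = topography_tally(pooled, montage)
    fig, ax = plt.subplots(figsize=(7, 4))
    if len(tally):
        pivot = (tally.groupby(["region", "hemisphere"])["count"].sum()
                      .unstack(fill_value=0))
        pivot.plot.bar(ax=ax)
        left, right = frontal_lr_ratio(tally)
        if right:
            ax.set_title(f"frontal left:right = {left}:{right} "
                         f"({left / right:.1f}:1)")
        else:
            ax.set_title(f"frontal left:right = {left}:0")
    ax.set_ylabel("pooled top-feature count")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig, tally
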
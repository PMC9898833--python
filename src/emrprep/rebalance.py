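"""Cluster-centroid undersampling of the majority class.

The majority class is clustered with k-means (Euclidean distance on z-scored
features) into as many clusters as majority samples wanted; because a
centroid is an average and not necessarily a real patient, the selected
representative of each cluster is the real member nearest its centroid.
Adjusting k yields any minority:majority ratio without other machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .cohort import Cohort

DEFAULT_RATIOS: tuple[tuple[int, int], ...] = ((1, 10), (1, 5), (1, 2), (1, 1))


@dataclass
class RatioDataset:
    """Row selection realizing one minority:majority ratio.

    ``ratio`` is the requested (minority, majority) pair, or ``None`` for the
    untouched original-ratio dataset.  ``indices`` point into the source
    cohort's rows (all minority rows plus the selected majority rows).
    """

    ratio: tuple[int, int] | None
    indices: np.ndarray
    provenance: dict

    def select(self, cohort: Cohort) -> Cohort:
        return cohort.subset_rows(self.indices)


def _standardize(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    return (X - mean) / std


def kmeans_undersample(majority_matrix, k: int, seed: int = 0,
                       n_init: int = 10) -> np.ndarray:
    """Select ``k`` real majority rows, one per k-means cluster.

    Features are z-scored before clustering (Euclidean distance is
    scale-sensitive across lab units).  Within each non-empty cluster the
    member with the smallest Euclidean distance to the converged centroid is
    chosen; ties break to the lowest row index.  If duplicate-heavy data
    leave clusters empty, the selected set is topped up greedily with the
    unselected row farthest from the current selection, so exactly ``k``
    distinct positional indices are always returned.
    """
    X = np.asarray(majority_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("majority_matrix must be 2-D")
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= {n}, got {k}")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute first")
    Z = _standardize(X)
    if k == n:
        return np.arange(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points => fewer centroids
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Z)
    labels = km.labels_
    selected: list[int] = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            continue
        d = np.linalg.norm(Z[members] - km.cluster_centers_[c], axis=1)
        selected.append(int(members[int(np.argmin(d))]))
    selected = sorted(set(selected))
    while len(selected) < k:  # empty-cluster fallback
        pool = np.setdiff1d(np.arange(n), selected)
        dist = np.min(
            np.linalg.norm(Z[pool][:, None, :] - Z[selected][None, :, :],
                           axis=2), axis=1)
        selected.append(int(pool[int(np.argmax(dist))]))
        selected = sorted(selected)
    return np.asarray(sorted(selected))


def ratio_to_k(n_minority: int, n_majority: int,
               ratio: tuple[int, int]) -> int:
    """Majority count implied by a (minority, majority) ratio, clamped."""
    a, b = ratio
    if a <= 0 or b <= 0:
        raise ValueError(f"ratio parts must be positive: {ratio}")
    k = int(round(n_minority * b / a))
    if k < 1:
        raise ValueError(f"ratio {a}:{b} implies k < 1 majority rows")
    return min(k, n_majority)


def build_ratio_datasets(cohort: Cohort,
                         ratios=DEFAULT_RATIOS, seed: int = 0,
                         minority_label: int = 1,
                         features: list[str] | None = None
                         ) -> list[RatioDataset]:
    """Realize each requested ratio by undersampling, plus the original.

    The minority class (positives by default) is always kept whole; per
    ratio (a, b) the majority class is undersampled to
    ``round(n_minority * b / a)`` rows.  The untouched original-ratio dataset
    is appended last so downstream evaluation can compare against it.
    """
    y = cohort.outcome.to_numpy()
    minority_idx = np.flatnonzero(y == minority_label)
    majority_idx = np.flatnonzero(y != minority_label)
    if minority_idx.size == 0 or majority_idx.size == 0:
        raise ValueError("both outcome classes must be present")
    if features is None:
        features = cohort.variables
    X_maj = cohort.data[features].to_numpy()[majority_idx]
    if np.isnan(X_maj).any():
        raise ValueError("cohort contains missing values; impute first")

    datasets: list[RatioDataset] = []
    for i, ratio in enumerate(ratios):
        k = ratio_to_k(minority_idx.size, majority_idx.size, tuple(ratio))
        sub_seed = (seed + 31 * (i + 1)) % (2**31 - 1)
        picked = kmeans_undersample(X_maj, k, seed=sub_seed)
        indices = np.sort(np.concatenate([minority_idx, majority_idx[picked]]))
        datasets.append(RatioDataset(
            ratio=tuple(ratio), indices=indices,
            provenance={"seed": sub_seed, "k": k, "n_init": 10}))
    datasets.append(RatioDataset(
        ratio=None, indices=np.arange(len(y)),
        provenance={"seed": seed, "k": majority_idx.size, "n_init": 0}))
    return datasets
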
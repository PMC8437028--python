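"""k-means clustering of per-interval allele-frequency changes.

Each significant locus is represented by its vector of allele-frequency
changes (dAF) between consecutive sampling days — the trajectory's shape,
decoupled from its absolute frequency level.  The number of clusters is
chosen by majority vote among internal validity indices computed over a
candidate range (silhouette width on Manhattan dissimilarities,
Calinski-Harabasz, Davies-Bouldin), then plain Euclidean k-means with many
random restarts performs the final grouping.  The pairing of a Manhattan
dissimilarity for k selection with Euclidean k-means for the clustering
itself is deliberate and kept as-is.

Cluster labels are renumbered 1..k by descending membership so that
"cluster 1" is always the largest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score, silhouette_score

DEFAULT_K_RANGE = range(2, 21)


@dataclass
class ClusteringResult:
    k: int
    assignments: pd.Series  # locus_id -> cluster label in 1..k
    centers: np.ndarray
    sizes: np.ndarray  # descending
    index_votes: dict = field(default_factory=dict)
    degenerate: bool = False


def compute_delta_af(days, means) -> np.ndarray:
    """First differences of a mean-MAF trajectory across consecutive days.

    Missing means (failed samples) are linearly interpolated on the
    day scale between flanking observed days; more than one consecutive
    missing value (or a missing endpoint) excludes the locus, raising
    ``ValueError`` so the caller can drop it with a warning.
    """
    days = np.asarray(days, dtype=float)
    means = np.asarray(means, dtype=float)
    if len(days) < 2:
        raise ValueError("trajectory needs at least two time points")
    missing = np.isnan(means)
    if missing.any():
        if missing[0] or missing[-1]:
            raise ValueError("missing endpoint mean cannot be interpolated")
        runs = np.diff(np.flatnonzero(~missing))
        if runs.max() > 2:
            raise ValueError("more than one consecutive missing time point")
        means = np.interp(days, days[~missing], means[~missing])
    return np.diff(means)


def build_delta_matrix(per_day_mean: pd.DataFrame, min_day: int = 2) -> tuple[pd.DataFrame, list]:
    """dAF matrix (loci x intervals) from a locus-by-day mean-MAF table.

    Days before ``min_day`` (the unreplicated egg pool) are excluded by
    default.  Returns the matrix and the list of loci dropped for
    uninterpolatable missingness.
    """
    days = sorted(d for d in per_day_mean.columns if d >= min_day)
    if len(days) < 2:
        raise ValueError("need at least two days to form intervals")
    cols = [f"d{a}_d{b}" for a, b in zip(days, days[1:])]
    rows, excluded = {}, []
    for locus, row in per_day_mean[days].iterrows():
        try:
            rows[locus] = compute_delta_af(days, row.to_numpy())
        except ValueError:
            excluded.append(locus)
    if excluded:
        warnings.warn(f"excluded {len(excluded)} loci from clustering (uninterpolatable missing means)")
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols), excluded


def select_k(delta: np.ndarray, k_range=DEFAULT_K_RANGE, seed: int = 0) -> tuple[int, dict, bool]:
    """Choose the cluster count by majority vote of internal validity indices.

    For each candidate k, k-means labels are scored by silhouette width
    (Manhattan dissimilarity), the Calinski-Harabasz ratio, and the
    Davies-Bouldin index; each index votes for its best k and the majority
    wins, ties broken toward smaller k.  All per-k scores are returned.
    Identical rows are degenerate: returns (1, votes, True).
    """
    X = np.asarray(delta, dtype=float)
    k_range = list(k_range)
    if np.allclose(X, X[0]):
        return 1, {}, True
    if X.shape[0] < max(k_range) + 1:
        raise ValueError(f"need more than {max(k_range)} rows to scan k up to {max(k_range)}")
    scores: dict[str, dict[int, float]] = {"silhouette": {}, "calinski_harabasz": {}, "davies_bouldin": {}}
    for k in k_range:
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        scores["silhouette"][k] = float(silhouette_score(X, labels, metric="manhattan"))
        scores["calinski_harabasz"][k] = float(calinski_harabasz_score(X, labels))
        scores["davies_bouldin"][k] = float(davies_bouldin_score(X, labels))
    votes = {
        "silhouette": max(scores["silhouette"], key=lambda k: (scores["silhouette"][k], -k)),
        "calinski_harabasz": max(scores["calinski_harabasz"], key=lambda k: (scores["calinski_harabasz"][k], -k)),
        "davies_bouldin": min(scores["davies_bouldin"], key=lambda k: (scores["davies_bouldin"][k], k)),
    }
    best = majority_vote(votes.values())
    return best, {"votes": votes, "scores": scores}, False


def majority_vote(candidate_ks) -> int:
    """The k with the most index votes; ties broken toward smaller k."""
    tally: dict[int, int] = {}
    for k in candidate_ks:
        tally[k] = tally.get(k, 0) + 1
    return max(tally.items(), key=lambda kv: (kv[1], -kv[0]))[0]


def cluster_trajectories(delta: pd.DataFrame, k: int, seed: int = 0, n_init: int = 25) -> ClusteringResult:
    """Euclidean k-means on the dAF matrix with labels ordered by membership."""
    X = delta.to_numpy(dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")
    if k == 1:
        labels = np.zeros(len(X), dtype=int)
        centers = X.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        labels, centers = km.labels_, km.cluster_centers_
    sizes = np.bincount(labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")  # descending membership, stable for ties
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    new_labels = relabel[labels]
    return ClusteringResult(
        k=k,
        assignments=pd.Series(new_labels, index=delta.index, name="cluster"),
        centers=centers[order],
        sizes=sizes[order],
    )
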
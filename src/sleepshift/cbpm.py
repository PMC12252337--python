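"""The cluster-based population model (CBPM).

An unsupervised domain-adaptation scheme for tabular session features:

1. *Tuning* — HDBSCAN's minimum-cluster-size and minimum-samples parameters
   are ablated over a grid; each configuration is scored by the silhouette
   coefficient of the non-noise training points, and the best is kept.
2. *Training* — the training sessions are clustered; noise points are
   excluded; one classifier is trained per cluster. A cluster containing a
   single class is augmented with opposite-class vectors drawn (seeded,
   without replacement) from the other clusters until balanced or exhausted.
3. *Inference* — a test vector is first assigned by nearest-training-point
   membership; if that neighbour is a noise point, it falls back to the
   nearest cluster centroid (Euclidean distance in standardized space, ties
   broken toward the lower cluster id). The assigned cluster's classifier
   predicts the label.

Clustering session feature vectors (rather than users) lets a single user's
nights land in different clusters, absorbing both interpersonal and
intra-personal variability without target-user labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.cluster import HDBSCAN
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

from .models import ClassifierSpec, SingleClassError
from .types import HIGH, LOW

__all__ = [
    "ClusterConfig",
    "ClusterModelBank",
    "NoClusterStructureError",
    "tune_hdbscan",
    "fit_cbpm",
    "assign_cluster",
    "cbpm_predict",
    "DEFAULT_MIN_CLUSTER_SIZES",
    "DEFAULT_MIN_SAMPLES",
]

DEFAULT_MIN_CLUSTER_SIZES = (5, 10, 15, 20, 25)
DEFAULT_MIN_SAMPLES = (1, 5, 10, 15)


class NoClusterStructureError(ValueError):
    """No grid configuration produced at least two clusters."""


@dataclass
class ClusterConfig:
    """A selected HDBSCAN configuration with its silhouette score."""

    min_cluster_size: int
    min_samples: int
    silhouette: float
    n_clusters: int
    grid_scores: list[dict] = field(default_factory=list, repr=False)


def _cluster_labels(Xs: np.ndarray, mcs: int, ms: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        return HDBSCAN(min_cluster_size=mcs, min_samples=ms, copy=True).fit_predict(Xs)


def _feature_order(X: np.ndarray) -> np.ndarray:
    """Lexicographic row order by feature values.

    Both tuning and fitting cluster in this canonical order: HDBSCAN's
    condensed-tree cuts can flip at boundary conditions under row
    permutation, so a configuration must be selected and reused on
    identically ordered input.
    """
    return np.lexsort(tuple(X[:, j] for j in range(X.shape[1] - 1, -1, -1)))


def tune_hdbscan(
    X: np.ndarray,
    min_cluster_sizes=DEFAULT_MIN_CLUSTER_SIZES,
    min_samples_grid=DEFAULT_MIN_SAMPLES,
) -> ClusterConfig:
    """Silhouette-guided ablation over the HDBSCAN hyperparameter grid.

    Every (min_cluster_size, min_samples) pair is evaluated on the z-scored
    training features; the silhouette is computed on points assigned to
    clusters (noise excluded). Configurations yielding fewer than two
    clusters score −1. Ties break toward the larger minimum cluster size.
    """
    X = np.asarray(X, dtype=float)
    smallest = min(min_cluster_sizes)
    if len(X) < 2 * smallest:
        raise ValueError(
            f"need at least {2 * smallest} training points, got {len(X)}"
        )
    X = X[_feature_order(X)]
    Xs = StandardScaler().fit_transform(X)
    scores: list[dict] = []
    best: tuple[float, int, int] | None = None
    best_k = 0
    for mcs, ms in product(min_cluster_sizes, min_samples_grid):
        labels = _cluster_labels(Xs, int(mcs), int(ms))
        mask = labels >= 0
        ids = np.unique(labels[mask])
        if len(ids) < 2 or mask.sum() <= len(ids):
            sil = -1.0
        else:
            sil = float(silhouette_score(Xs[mask], labels[mask]))
        scores.append(
            {"min_cluster_size": int(mcs), "min_samples": int(ms),
             "silhouette": sil, "n_clusters": int(len(ids))}
        )
        key = (sil, int(mcs), int(ms))
        if best is None or key > best:
            best = key
            best_k = int(len(ids))
    assert best is not None
    if best[0] <= -1.0:
        raise NoClusterStructureError(
            "no configuration yields >= 2 clusters; revise the hyperparameter grids"
        )
    return ClusterConfig(
        min_cluster_size=best[1],
        min_samples=best[2],
        silhouette=best[0],
        n_clusters=best_k,
        grid_scores=scores,
    )


@dataclass
class ClusterModelBank:
    """Fitted CBPM state: clusterer output, centroids, one model per cluster."""

    scaler: StandardScaler
    train_points: np.ndarray  # standardized, includes noise points
    train_cluster_labels: np.ndarray  # -1 marks noise
    cluster_ids: list[int]
    centroids: dict[int, np.ndarray]
    models: dict[int, object]
    config: ClusterConfig
    n_noise: int
    n_augmented: dict[int, int]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Feature order with the label as a final tie-break for duplicates."""
    keys = tuple(X[:, j] for j in range(X.shape[1] - 1, -1, -1))
    return np.lexsort(((y == HIGH).astype(int),) + keys)


def fit_cbpm(
    X: np.ndarray,
    y: np.ndarray,
    config: ClusterConfig,
    spec: ClassifierSpec,
    seed: int = 0,
) -> ClusterModelBank:
    """Cluster the training set and train one classifier per cluster.

    Noise points are excluded from every cluster's training set. Single-class
    clusters are augmented with opposite-class vectors sampled uniformly
    without replacement from the other clusters until the minority count
    reaches min(majority count, available). Centroids are the means of the
    original (non-augmented) members in standardized space.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    order = _canonical_order(X, y)
    X, y = X[order], y[order]

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    labels = _cluster_labels(Xs, config.min_cluster_size, config.min_samples)
    ids = sorted(int(c) for c in np.unique(labels) if c >= 0)
    if not ids:
        raise NoClusterStructureError("every training point was labelled noise")

    rng = np.random.default_rng(seed)
    centroids: dict[int, np.ndarray] = {}
    models: dict[int, object] = {}
    n_augmented: dict[int, int] = {}
    for cid in ids:
        members = np.flatnonzero(labels == cid)
        centroids[cid] = Xs[members].mean(axis=0)
        Xc, yc = Xs[members], y[members]
        present = np.unique(yc)
        n_aug = 0
        if len(present) < 2:
            missing = LOW if present[0] == HIGH else HIGH
            pool = np.flatnonzero((labels >= 0) & (labels != cid) & (y == missing))
            need = min(len(members), len(pool))
            if need == 0:
                raise SingleClassError(
                    f"cluster {cid} is single-class and no opposite-class "
                    "vectors exist in the other clusters"
                )
            picked = rng.choice(pool, size=need, replace=False)
            Xc = np.vstack([Xc, Xs[picked]])
            yc = np.concatenate([yc, y[picked]])
            n_aug = int(need)
        n_augmented[cid] = n_aug
        clf = spec.make(seed)
        clf.fit(Xc, yc)
        models[cid] = clf

    return ClusterModelBank(
        scaler=scaler,
        train_points=Xs,
        train_cluster_labels=labels,
        cluster_ids=ids,
        centroids=centroids,
        models=models,
        config=config,
        n_noise=int(np.sum(labels < 0)),
        n_augmented=n_augmented,
    )


def assign_cluster(bank: ClusterModelBank, x: np.ndarray) -> int:
    """Assign one feature vector to a cluster; the fallback always resolves.

    Membership first follows the clusterer: the vector inherits the cluster
    of its nearest training point. If that neighbour was labelled noise, the
    vector is assigned to the nearest cluster centroid instead (Euclidean
    distance in standardized space; ties break toward the lower cluster id).
    """
    xs = bank.scaler.transform(np.asarray(x, dtype=float).reshape(1, -1))[0]
    d_train = np.linalg.norm(bank.train_points - xs, axis=1)
    nearest = int(np.argmin(d_train))
    label = int(bank.train_cluster_labels[nearest])
    if label >= 0:
        return label
    d_cent = np.array([np.linalg.norm(bank.centroids[c] - xs) for c in bank.cluster_ids])
    return bank.cluster_ids[int(np.argmin(d_cent))]


def cbpm_predict(bank: ClusterModelBank, X: np.ndarray) -> np.ndarray:
    """Predict labels by routing each vector to its cluster's classifier."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    preds = []
    for row in X:
        cid = assign_cluster(bank, row)
        xs = bank.scaler.transform(row.reshape(1, -1))
        preds.append(bank.models[cid].predict(xs)[0])
    return np.array(preds)
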
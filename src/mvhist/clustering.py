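"""Multi-view late-integration clustering.

Per view: features are grouped by Ward hierarchical clustering under a
correlation-based distance (1 - |Pearson r|), each feature cluster is
represented by its correlation medoid (the "centroid feature"), and
patients are Ward-clustered on the standardized centroid features.  The
per-view patient partitions are then integrated — by Ward clustering of the
stacked binary membership matrices (default) or by a spectral cut of the
patient co-association matrix — into the final two patient clusters.

Cluster counts are chosen by average silhouette over a candidate range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

DEFAULT_K_RANGE = range(2, 11)


@dataclass
class FeatureView:
    """One view's standardized patients × features matrix."""

    name: str
    matrix: pd.DataFrame  # standardized: columns mean 0, sd 1

    @classmethod
    def from_raw(cls, name: str, raw: pd.DataFrame) -> "FeatureView":
        """Standardize columns to mean 0 / sd 1 (constant columns become 0)."""
        if raw.isna().any().any():
            raise ValueError(f"view {name!r} contains missing values")
        Z = raw.astype(float)
        sd = Z.std(axis=0, ddof=0)
        sd = sd.where(sd > 0, 1.0)
        return cls(name=name, matrix=(Z - Z.mean(axis=0)) / sd)

    @property
    def feature_names(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def patient_ids(self) -> list:
        return list(self.matrix.index)


@dataclass
class FeatureClustering:
    labels: np.ndarray  # per feature, 1..k
    k: int
    feature_names: list[str]


@dataclass
class CentroidSet:
    """Selected centroid features per feature cluster of one view."""

    view: str
    centroids: list[str]
    memberships: dict[str, list[str]]  # centroid -> its feature cluster


@dataclass
class FinalClustering:
    per_view_labels: dict[str, np.ndarray]
    final_labels: np.ndarray  # values in 1..final_k, 1 = largest cluster
    per_view_k: dict[str, int]
    patient_ids: list


@dataclass
class MVDAConfig:
    feature_k_candidates: Iterable[int] = field(default_factory=lambda: DEFAULT_K_RANGE)
    patient_k_candidates: Iterable[int] = field(default_factory=lambda: DEFAULT_K_RANGE)
    final_k: int = 2
    integration: str = "ward"  # or "spectral"


@dataclass
class MVDAResult:
    clustering: FinalClustering
    centroid_sets: dict[str, CentroidSet]
    feature_clusterings: dict[str, FeatureClustering]

    @property
    def final_labels(self) -> np.ndarray:
        return self.clustering.final_labels

    def centroid_features(self) -> list[str]:
        out = []
        for cs in self.centroid_sets.values():
            out.extend(cs.centroids)
        return out


def _ward_labels(dist_condensed: np.ndarray, k: int) -> np.ndarray:
    Z = linkage(dist_condensed, method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def _choose_k(
    dist: np.ndarray, candidates: Sequence[int], metric: str = "precomputed"
) -> int:
    """Average-silhouette model selection over the admissible candidates."""
    n = dist.shape[0]
    condensed = squareform(dist, checks=False)
    best_k, best_s = None, -np.inf
    for k in candidates:
        if not 2 <= k <= n - 1:
            continue
        labels = _ward_labels(condensed, k)
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(dist, labels, metric=metric)
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_k is None:
        # no candidate admits a silhouette (e.g. k == n); fall back
        best_k = min(max(candidates), n)
    return int(best_k)


def correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """Pairwise 1 - |Pearson r| between columns (NaN correlations -> distance 1)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = np.corrcoef(np.asarray(matrix, dtype=float), rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    d = 1.0 - np.abs(r)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def cluster_features(
    view: FeatureView, k_candidates: Iterable[int] = DEFAULT_K_RANGE
) -> FeatureClustering:
    """Ward-cluster the view's features under correlation distance."""
    names = view.feature_names
    n = len(names)
    if n < 2:
        raise ValueError(f"view {view.name!r}: need >= 2 features")
    candidates = list(k_candidates)
    if max(candidates) > n:
        raise ValueError(
            f"k candidates up to {max(candidates)} exceed the {n} features of view {view.name!r}"
        )
    dist = correlation_distance(view.matrix.to_numpy())
    k = _choose_k(dist, candidates)
    labels = _ward_labels(squareform(dist, checks=False), k)
    return FeatureClustering(labels=labels, k=k, feature_names=names)


def select_centroids(view: FeatureView, clusters: FeatureClustering) -> CentroidSet:
    """Correlation medoid of every feature cluster.

    The centroid of a cluster is the member feature with the highest mean
    absolute Pearson correlation to the other members; singleton clusters
    select their only feature; ties break toward the earliest column.
    """
    X = view.matrix.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = np.corrcoef(X, rowvar=False)
    r = np.abs(np.nan_to_num(np.atleast_2d(r), nan=0.0))
    centroids, memberships = [], {}
    for c in np.unique(clusters.labels):
        idx = np.nonzero(clusters.labels == c)[0]
        members = [clusters.feature_names[i] for i in idx]
        if len(idx) == 1:
            best = members[0]
        else:
            sub = r[np.ix_(idx, idx)]
            mean_abs = (sub.sum(axis=1) - 1.0) / (len(idx) - 1)
            best = members[int(np.argmax(mean_abs))]  # argmax: first wins ties
        centroids.append(best)
        memberships[best] = members
    return CentroidSet(view=view.name, centroids=centroids, memberships=memberships)


def cluster_patients_view(
    view: FeatureView,
    centroid_names: Sequence[str],
    k_candidates: Iterable[int] = DEFAULT_K_RANGE,
) -> tuple[np.ndarray, int]:
    """Ward patient clustering on Euclidean distance over centroid features."""
    if len(centroid_names) < 1:
        raise ValueError("need at least one centroid feature")
    X = view.matrix[list(centroid_names)].to_numpy()
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two patients")
    candidates = list(k_candidates)
    if max(candidates) > n:
        raise ValueError(
            f"k candidates up to {max(candidates)} exceed the {n} patients"
        )
    if np.allclose(X, X[0]):
        warnings.warn(
            f"view {view.name!r}: all patients identical; single cluster",
            stacklevel=2,
        )
        return np.ones(n, dtype=int), 1
    from scipy.spatial.distance import pdist

    dcond = pdist(X, metric="euclidean")
    dist = squareform(dcond)
    best_k, best_s = None, -np.inf
    for k in candidates:
        if not 2 <= k <= n - 1:
            continue
        labels = _ward_labels(dcond, k)
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(dist, labels, metric="precomputed")
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_k is None:
        best_k = min(max(candidates), n)
    return _ward_labels(dcond, best_k), int(best_k)


def _membership_matrix(labels: np.ndarray) -> np.ndarray:
    """Label-free binary membership encoding (one column per cluster)."""
    labels = np.asarray(labels)
    cats = np.unique(labels)
    return (labels[:, None] == cats[None, :]).astype(float)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Map cluster ids to 1..k by decreasing size (ties: first occurrence)."""
    cats, counts = np.unique(labels, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    mapping = {cats[o]: i + 1 for i, o in enumerate(order)}
    return np.array([mapping[l] for l in labels])


def integrate_views(
    per_view_labels: Mapping[str, np.ndarray],
    final_k: int = 2,
    strategy: str = "ward",
    patient_ids: Sequence | None = None,
    random_state: int = 0,
) -> FinalClustering:
    """Late integration of the per-view patient partitions.

    Per-view labels are encoded as binary membership matrices and stacked;
    ``strategy="ward"`` clusters patients on the stacked encoding, while
    ``strategy="spectral"`` partitions the co-association matrix (fraction of
    views agreeing on each pair).  Final labels are renumbered so cluster 1
    is the largest.
    """
    if strategy not in ("ward", "spectral"):
        raise ValueError(f"unknown integration strategy {strategy!r}")
    views = dict(per_view_labels)
    lengths = {v: len(np.asarray(l)) for v, l in views.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"views label different patient sets: {lengths}")
    n = next(iter(lengths.values()))
    if final_k > n:
        raise ValueError(f"final_k={final_k} exceeds {n} patients")
    if patient_ids is None:
        patient_ids = list(range(n))
    stacked = np.hstack([_membership_matrix(np.asarray(l)) for l in views.values()])
    if final_k == n:
        final = np.arange(1, n + 1)
    elif strategy == "ward":
        from scipy.spatial.distance import pdist

        final = _ward_labels(pdist(stacked, metric="euclidean"), final_k)
    else:
        from sklearn.cluster import SpectralClustering

        assoc = np.zeros((n, n))
        for l in views.values():
            l = np.asarray(l)
            assoc += (l[:, None] == l[None, :]).astype(float)
        assoc /= len(views)
        sc = SpectralClustering(
            n_clusters=final_k, affinity="precomputed", random_state=random_state
        )
        final = sc.fit_predict(assoc) + 1
    final = _relabel_by_size(final)
    return FinalClustering(
        per_view_labels={v: np.asarray(l) for v, l in views.items()},
        final_labels=final,
        per_view_k={v: len(np.unique(l)) for v, l in views.items()},
        patient_ids=list(patient_ids),
    )


def run_mvda(
    view_frames: Mapping[str, pd.DataFrame],
    config: MVDAConfig | None = None,
) -> MVDAResult:
    """Full multi-view pipeline on raw (unstandardized) per-view frames.

    Standardization is (re)fit here, so leave-one-out reruns never leak the
    held-out patient.  Candidate k ranges are clamped to what the data admit.
    """
    config = config if config is not None else MVDAConfig()
    ids = None
    per_view_labels: dict[str, np.ndarray] = {}
    centroid_sets: dict[str, CentroidSet] = {}
    feature_clusterings: dict[str, FeatureClustering] = {}
    for name, raw in view_frames.items():
        if ids is None:
            ids = list(raw.index)
        elif list(raw.index) != ids:
            raise ValueError(f"view {name!r} has a different patient set")
        view = FeatureView.from_raw(name, raw)
        n_feat = len(view.feature_names)
        n_pat = len(ids)
        fk = [k for k in config.feature_k_candidates if k <= n_feat] or [min(2, n_feat)]
        pk = [k for k in config.patient_k_candidates if k <= n_pat] or [min(2, n_pat)]
        fc = cluster_features(view, fk)
        cs = select_centroids(view, fc)
        labels, _ = cluster_patients_view(view, cs.centroids, pk)
        per_view_labels[name] = labels
        centroid_sets[name] = cs
        feature_clusterings[name] = fc
    clustering = integrate_views(
        per_view_labels,
        final_k=config.final_k,
        strategy=config.integration,
        patient_ids=ids,
    )
    return MVDAResult(
        clustering=clustering,
        centroid_sets=centroid_sets,
        feature_clusterings=feature_clusterings,
    )
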
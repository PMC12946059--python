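"""Discovery stage: extreme-outcome patient selection and the tile-level
PCA + hierarchical-clustering (HCPC) model.

The discovery set is the k patients with the longest event-free follow-up
("responders") plus the k progressed patients with the shortest time to
progression ("non-responders"), k=5 by default. Their tiles are reduced by
PCA (components retained until 80% of variance, capped at 50, unless fixed)
and clustered with Ward-linkage agglomeration cut at k=3, optionally
consolidated by a k-means pass seeded at the cut's cluster means so that
every training tile's nearest centroid is its own cluster -- the property
that makes projection-time nearest-centroid assignment faithful. Clusters
are renumbered by descending size with a deterministic tie-break.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "ExtremeSelection",
    "PCAModel",
    "ClusterModel",
    "ProjectionModel",
    "select_extremes",
    "fit_pca",
    "fit_hcpc",
    "compute_centroids",
]


@dataclass
class ExtremeSelection:
    responder_ids: list[str]
    nonresponder_ids: list[str]
    k: int = 5

    def __post_init__(self) -> None:
        if set(self.responder_ids) & set(self.nonresponder_ids):
            raise ValueError("responder and non-responder lists must be disjoint")

    @property
    def all_ids(self) -> list[str]:
        return list(self.responder_ids) + list(self.nonresponder_ids)


def select_extremes(
    survival: pd.DataFrame,
    k: int = 5,
    time_col: str = "time_months",
    event_col: str = "event",
) -> ExtremeSelection:
    """k longest event-free survivors and k fastest progressors.

    Ties in time are broken by lexicographic patient id, making the
    selection deterministic.
    """
    censored = survival[survival[event_col] == 0]
    progressed = survival[survival[event_col] == 1]
    if len(censored) < k:
        raise ValueError(f"need >= {k} event-free patients, have {len(censored)}")
    if len(progressed) < k:
        raise ValueError(f"need >= {k} progressed patients, have {len(progressed)}")
    responders = (
        censored.sort_values([time_col, "patient_id"], ascending=[False, True])
        .head(k)["patient_id"]
        .tolist()
    )
    nonresponders = (
        progressed.sort_values([time_col, "patient_id"], ascending=[True, True])
        .head(k)["patient_id"]
        .tolist()
    )
    return ExtremeSelection(responders, nonresponders, k=k)


@dataclass
class PCAModel:
    """Frozen PCA: center (and optional scale) plus orthonormal loadings."""

    center: np.ndarray
    loadings: np.ndarray  # n_features x n_components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        self.loadings = np.asarray(self.loadings, float)
        g = self.loadings.T @ self.loadings
        if not np.allclose(g, np.eye(g.shape[0]), atol=1e-8):
            raise ValueError("loadings columns must be orthonormal")
        ev = np.asarray(self.explained_variance, float)
        if np.any(np.diff(ev) > 1e-10):
            raise ValueError("explained_variance must be non-increasing")
        self.explained_variance = ev
        self.explained_variance_ratio = np.asarray(self.explained_variance_ratio, float)
        if self.scale is not None:
            self.scale = np.asarray(self.scale, float)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.shape[1] != self.center.size:
            raise ValueError(
                f"feature length {X.shape[1]} does not match model ({self.center.size})"
            )
        Z = X - self.center
        if self.scale is not None:
            Z = Z / self.scale
        return Z @ self.loadings


def fit_pca(
    X: np.ndarray,
    n_components: int | None = None,
    scale: bool = False,
    variance_target: float = 0.80,
    max_components: int = 50,
) -> tuple[PCAModel, np.ndarray]:
    """Centered (optionally unit-scaled) PCA with a deterministic sign convention.

    When ``n_components`` is None, the smallest number of components
    explaining ``variance_target`` of the variance is retained, capped at
    ``max_components``. Each loading column is flipped so its
    largest-magnitude entry is positive.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if n < 1 or p < 1:
        raise ValueError("empty feature matrix")
    sd = None
    work = X
    if scale:
        sd = np.maximum(X.std(axis=0, ddof=1), 1e-12)
        work = X / sd  # PCA centers internally; scores equal ((X - mean)/sd) @ L
    full_rank = min(n, p)
    pca = PCA(n_components=full_rank, svd_solver="full")
    pca.fit(work)
    rank = int(np.sum(pca.explained_variance_ > 1e-12))
    if n_components is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        m = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        m = min(m, max_components, rank)
    else:
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        m = int(n_components)
        if m > rank:
            warnings.warn(
                f"requested {m} components but rank is {rank}; truncating",
                RuntimeWarning,
                stacklevel=2,
            )
            m = rank
    loadings = pca.components_[:m].T.copy()  # p x m
    for jcol in range(m):  # sign convention
        idx = int(np.argmax(np.abs(loadings[:, jcol])))
        if loadings[idx, jcol] < 0:
            loadings[:, jcol] = -loadings[:, jcol]
    center = X.mean(axis=0) if scale else pca.mean_
    model = PCAModel(
        center=center,
        loadings=loadings,
        explained_variance=pca.explained_variance_[:m],
        explained_variance_ratio=pca.explained_variance_ratio_[:m],
        scale=sd,
    )
    # scores via the frozen transform so later projection of the training
    # tiles reproduces them bit-for-bit
    return model, model.transform(X)


@dataclass
class ClusterModel:
    """Ward/k-means tile clustering in PC space."""

    k: int
    labels: np.ndarray  # 1..k, aligned with the training score rows
    centroids: np.ndarray  # k x n_components
    linkage_record: np.ndarray | None = None
    consolidated: bool = True
    tile_ids: list[str] | None = None

    @property
    def tile_labels(self) -> dict[str, int]:
        if self.tile_ids is None:
            raise ValueError("no tile ids recorded")
        return {t: int(l) for t, l in zip(self.tile_ids, self.labels)}


def compute_centroids(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Arithmetic mean of member scores per cluster label 1..k."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    k = labels.max()
    if set(np.unique(labels)) != set(range(1, k + 1)):
        raise ValueError("labels must cover 1..k with no empty cluster")
    return np.vstack([scores[labels == c].mean(axis=0) for c in range(1, k + 1)])


def _renumber_by_size(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Renumber clusters by descending size; ties by centroid first coordinate."""
    labs = np.unique(labels)
    sizes = {c: int(np.sum(labels == c)) for c in labs}
    firsts = {c: float(scores[labels == c].mean(axis=0)[0]) for c in labs}
    order = sorted(labs, key=lambda c: (-sizes[c], firsts[c]))
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[c] for c in labels], int)


def fit_hcpc(
    scores: np.ndarray,
    k: int = 3,
    consolidate: bool = True,
    tile_ids: list[str] | None = None,
) -> ClusterModel:
    """Ward-linkage agglomerative clustering on PC scores, cut at k.

    With ``consolidate`` (default), a k-means pass seeded at the cut's
    cluster means refines the partition until convergence, guaranteeing the
    nearest-centroid self-consistency invariant.
    """
    scores = np.asarray(scores, float)
    if scores.ndim != 2 or scores.shape[0] < k:
        raise ValueError("need at least k score rows")
    if np.unique(scores, axis=0).shape[0] < k:
        raise ValueError("fewer than k distinct points")
    Z = linkage(scores, method="ward")  # Euclidean; Lance-Williams update
    labels = fcluster(Z, t=k, criterion="maxclust")
    if consolidate:
        init = np.vstack([scores[labels == c].mean(axis=0) for c in np.unique(labels)])
        km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=300, random_state=0)
        labels = km.fit_predict(scores) + 1
    labels = _renumber_by_size(labels, scores)
    centroids = compute_centroids(scores, labels)
    return ClusterModel(
        k=k,
        labels=labels,
        centroids=centroids,
        linkage_record=Z,
        consolidated=consolidate,
        tile_ids=tile_ids,
    )


@dataclass
class ProjectionModel:
    """The trained classifier artifact: frozen PCA + cluster centroids."""

    pca: PCAModel
    centroids: np.ndarray
    k: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, float)
        if self.centroids.shape != (self.k, self.pca.n_components):
            raise ValueError("centroids must be k x n_components")

    def to_dict(self) -> dict:
        return {
            "center": self.pca.center.tolist(),
            "scale": None if self.pca.scale is None else self.pca.scale.tolist(),
            "loadings": self.pca.loadings.tolist(),
            "explained_variance": self.pca.explained_variance.tolist(),
            "explained_variance_ratio": self.pca.explained_variance_ratio.tolist(),
            "centroids": self.centroids.tolist(),
            "k": self.k,
            "metadata": self.metadata,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionModel":
        pca = PCAModel(
            center=np.asarray(d["center"]),
            loadings=np.asarray(d["loadings"]),
            explained_variance=np.asarray(d["explained_variance"]),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"]),
            scale=None if d.get("scale") is None else np.asarray(d["scale"]),
        )
        return cls(pca=pca, centroids=np.asarray(d["centroids"]), k=int(d["k"]),
                   metadata=d.get("metadata", {}))

    @classmethod
    def load(cls, path) -> "ProjectionModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def content_hash(self) -> str:
        """sha256 of the canonical JSON serialization (frozen-model contract)."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()
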
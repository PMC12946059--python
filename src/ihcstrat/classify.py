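"""Frozen-space classification of held-out tiles and patients.

New tiles are projected a posteriori into the discovery PCA space (no model
parameter is re-estimated), labelled by nearest centroid, aggregated to the
patient level by majority voting over tile labels, and the k tile clusters
are merged into two prognostic groups (High / Low). The default merge maps
clusters {1, 2} to High and cluster 3 to Low; a data-driven variant merges
clusters whose training-cohort survival is indistinguishable by pairwise
log-rank tests and labels the better-surviving block High.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .discovery import ProjectionModel
from .features import TileFeatureTable

__all__ = [
    "PatientAssignment",
    "MergeRule",
    "UnclassifiablePatientError",
    "project_tiles",
    "assign_tiles",
    "vote_patient",
    "merge_to_dl_group",
    "classify_cohort",
    "data_driven_merge",
]

log = logging.getLogger(__name__)


class UnclassifiablePatientError(ValueError):
    """Raised for a patient with no (or too few) classifiable tiles."""


@dataclass
class MergeRule:
    """Total map cluster index -> {"High", "Low"}."""

    mapping: Mapping[int, str] = field(default_factory=lambda: {1: "High", 2: "High", 3: "Low"})

    def __post_init__(self) -> None:
        for c, g in self.mapping.items():
            if g not in ("High", "Low"):
                raise ValueError(f"cluster {c} mapped to {g!r}; expected 'High' or 'Low'")

    def __call__(self, cluster: int) -> str:
        return merge_to_dl_group(cluster, self)


@dataclass
class PatientAssignment:
    patient_id: str
    counts: dict[int, int]
    assigned_cluster: int
    dl_group: str | None
    n_tiles: int
    tie_flag: bool = False

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_tiles:
            raise ValueError("tile counts must sum to n_tiles")


def project_tiles(features, model: ProjectionModel) -> np.ndarray:
    """Project feature vectors into the frozen PCA space.

    ``features`` may be a TileFeatureTable or a plain (n, p) array. The
    model is never mutated (frozen contract).
    """
    X = features.X if isinstance(features, TileFeatureTable) else np.asarray(features, float)
    return model.pca.transform(X)


def assign_tiles(scores: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels 1..k; exact ties go to the lowest index."""
    scores = np.atleast_2d(np.asarray(scores, float))
    centroids = np.asarray(centroids, float)
    if centroids.ndim != 2 or centroids.shape[0] < 1:
        raise ValueError("need at least one centroid")
    if scores.shape[1] != centroids.shape[1]:
        raise ValueError("score/centroid dimension mismatch")
    d = cdist(scores, centroids)
    return d.argmin(axis=1) + 1  # argmin returns the first (lowest) index on ties


def vote_patient(
    tile_labels: np.ndarray,
    patient_id: str = "",
    k: int | None = None,
    min_tiles: int = 1,
) -> PatientAssignment:
    """Majority vote over one patient's tile labels.

    Ties go to the lowest cluster index and are flagged (and logged).
    """
    labels = np.asarray(tile_labels, int)
    if labels.size < max(1, min_tiles):
        raise UnclassifiablePatientError(
            f"patient {patient_id!r} has {labels.size} tiles; need >= {max(1, min_tiles)}"
        )
    kk = int(k if k is not None else labels.max())
    counts = {c: int(np.sum(labels == c)) for c in range(1, kk + 1)}
    best = max(counts.values())
    winners = [c for c, n in counts.items() if n == best]
    assigned = min(winners)
    tie = len(winners) > 1
    if tie:
        log.info("patient %s: vote tie between clusters %s; assigned %d",
                 patient_id, winners, assigned)
    return PatientAssignment(
        patient_id=patient_id,
        counts=counts,
        assigned_cluster=assigned,
        dl_group=None,
        n_tiles=int(labels.size),
        tie_flag=tie,
    )


def merge_to_dl_group(assigned_cluster: int, rule: MergeRule) -> str:
    if assigned_cluster not in rule.mapping:
        raise KeyError(f"cluster {assigned_cluster} not covered by the merge rule")
    return rule.mapping[assigned_cluster]


def classify_cohort(
    table: TileFeatureTable,
    model: ProjectionModel,
    rule: MergeRule | None = None,
    min_tiles: int = 1,
) -> pd.DataFrame:
    """Project, assign, vote, and merge for every patient in a feature table.

    Returns one row per patient: patient_id, n_tiles, count_1..count_k,
    assigned_cluster, dl_group, tie_flag. Tile and patient order do not
    affect the result.
    """
    rule = rule or MergeRule()
    scores = project_tiles(table, model)
    tile_lab = assign_tiles(scores, model.centroids)
    df = table.frame[["patient_id", "cohort"]].copy()
    df["tile_cluster"] = tile_lab
    rows = []
    for pid in sorted(df["patient_id"].unique()):
        sub = df[df["patient_id"] == pid]
        pa = vote_patient(sub["tile_cluster"].to_numpy(), pid, k=model.k, min_tiles=min_tiles)
        row = {
            "patient_id": pid,
            "cohort": sub["cohort"].iloc[0],
            "n_tiles": pa.n_tiles,
            **{f"count_{c}": pa.counts.get(c, 0) for c in range(1, model.k + 1)},
            "assigned_cluster": pa.assigned_cluster,
            "dl_group": merge_to_dl_group(pa.assigned_cluster, rule),
            "tie_flag": pa.tie_flag,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def data_driven_merge(
    assignments: pd.DataFrame,
    survival: pd.DataFrame,
    alpha: float = 0.05,
    force_two: bool = True,
    time_col: str = "time_months",
    event_col: str = "event",
) -> MergeRule:
    """Outcome-based merge: clusters with indistinguishable survival coalesce.

    Pairwise two-group log-rank tests are run between patient-level
    clusters; while more than two blocks remain, the pair with the largest
    p-value is merged if p >= ``alpha`` (or unconditionally when
    ``force_two``, which guarantees a two-group rule). The block with the
    longer restricted mean survival becomes "High".
    """
    from lifelines.statistics import logrank_test as _lr

    merged = survival.merge(
        assignments[["patient_id", "assigned_cluster"]], on="patient_id"
    )
    clusters = sorted(merged["assigned_cluster"].unique())
    blocks: list[set[int]] = [{c} for c in clusters]

    def block_frame(b: set[int]) -> pd.DataFrame:
        return merged[merged["assigned_cluster"].isin(b)]

    while len(blocks) > 2:
        best_p, best_pair = -1.0, None
        for i in range(len(blocks)):
            for j in range(i + 1, len(blocks)):
                a, b = block_frame(blocks[i]), block_frame(blocks[j])
                r = _lr(a[time_col], b[time_col], a[event_col], b[event_col])
                if r.p_value > best_p:
                    best_p, best_pair = r.p_value, (i, j)
        if best_p < alpha and not force_two:
            break
        i, j = best_pair
        blocks[i] = blocks[i] | blocks[j]
        del blocks[j]
    if len(blocks) != 2:
        raise ValueError(
            f"merge produced {len(blocks)} blocks; rerun with force_two=True for a 2-group rule"
        )

    def restricted_mean(b: set[int]) -> float:
        sub = block_frame(b)
        tau = merged[time_col].max()
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter().fit(sub[time_col], sub[event_col])
        from lifelines.utils import restricted_mean_survival_time

        return float(restricted_mean_survival_time(km, t=tau))

    r0, r1 = restricted_mean(blocks[0]), restricted_mean(blocks[1])
    high, low = (blocks[0], blocks[1]) if r0 >= r1 else (blocks[1], blocks[0])
    mapping = {int(c): "High" for c in high}
    mapping.update({int(c): "Low" for c in low})
    return MergeRule(mapping=mapping)
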
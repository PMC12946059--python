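"""Tile feature table, pluggable embedder interface, and reference-cohort
feature-wise normalization.

The embedder is deliberately external: any callable mapping an RGB tile to a
fixed-length real vector works (the study used a frozen pathology foundation
model producing 1,024-dim embeddings; toy embedders are enough to exercise
the plumbing). Normalization standardizes *every* cohort by the reference
cohort's per-feature mean and standard deviation, so the reference cohort
ends up with mean 0 / sd 1 and other cohorts retain their offsets expressed
in reference-sd units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TileFeatureTable",
    "ReferenceStats",
    "embed_tiles",
    "compute_reference_stats",
    "apply_reference_norm",
]

ID_COLS = ("patient_id", "cohort", "tile_id")
SD_FLOOR = 1e-8


def _feature_name(i: int, n: int) -> str:
    width = max(4, len(str(n)))
    return f"f{i + 1:0{width}d}"


class TileFeatureTable:
    """One row per tile: patient id, cohort id, and a fixed-length feature vector.

    Backed by a pandas DataFrame with columns ``patient_id, cohort, tile_id,
    f0001..fNNNN``. Invariants checked on construction: a single feature
    length, unique tile ids, no missing values.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in ID_COLS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing id columns: {missing}")
        feats = [c for c in frame.columns if c not in ID_COLS]
        if not feats:
            raise ValueError("feature table has no feature columns")
        if frame["tile_id"].duplicated().any():
            raise ValueError("duplicate tile_id values")
        fblock = frame[feats]
        if fblock.isna().any().any() or frame[list(ID_COLS)].isna().any().any():
            raise ValueError("feature table contains missing values")
        if not all(np.issubdtype(dt, np.number) for dt in fblock.dtypes):
            raise ValueError("feature columns must be numeric")
        self.frame = frame.reset_index(drop=True)
        self._feature_cols = feats

    # -- construction ------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        patient_ids: Sequence[str],
        cohorts: Sequence[str],
        tile_ids: Sequence[str],
        X: np.ndarray,
    ) -> "TileFeatureTable":
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[0] != len(tile_ids):
            raise ValueError("X must be (n_tiles, n_features)")
        ids = pd.DataFrame(
            {"patient_id": list(patient_ids), "cohort": list(cohorts), "tile_id": list(tile_ids)}
        )
        feats = pd.DataFrame(
            X, columns=[_feature_name(i, X.shape[1]) for i in range(X.shape[1])]
        )
        return cls(pd.concat([ids, feats], axis=1))

    # -- accessors ---------------------------------------------------------
    @property
    def feature_columns(self) -> list[str]:
        return list(self._feature_cols)

    @property
    def n_features(self) -> int:
        return len(self._feature_cols)

    @property
    def X(self) -> np.ndarray:
        return self.frame[self._feature_cols].to_numpy(float)

    def __len__(self) -> int:
        return len(self.frame)

    def subset_cohort(self, cohort: str) -> "TileFeatureTable":
        sub = self.frame[self.frame["cohort"] == cohort]
        if sub.empty:
            raise ValueError(f"no tiles for cohort {cohort!r}")
        return TileFeatureTable(sub.copy())

    def subset_patients(self, patient_ids: Iterable[str]) -> "TileFeatureTable":
        wanted = set(patient_ids)
        sub = self.frame[self.frame["patient_id"].isin(wanted)]
        if sub.empty:
            raise ValueError("no tiles for the requested patients")
        return TileFeatureTable(sub.copy())

    # -- io ----------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_parquet(self, path) -> None:
        self.frame.to_parquet(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "TileFeatureTable":
        return cls(pd.read_csv(path))

    @classmethod
    def read_parquet(cls, path) -> "TileFeatureTable":
        return cls(pd.read_parquet(path))


@dataclass
class ReferenceStats:
    """Per-feature mean and standard deviation of the reference cohort."""

    mean: np.ndarray
    sd: np.ndarray
    n_reference: int
    reference_cohort: str

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.sd = np.asarray(self.sd, float)
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise ValueError("mean and sd must be 1-D vectors of equal length")
        if np.any(self.sd < 0):
            raise ValueError("sd must be nonnegative")

    @property
    def n_features(self) -> int:
        return self.mean.size

    def to_json(self, path) -> None:
        payload = {
            "reference_cohort": self.reference_cohort,
            "n_reference": int(self.n_reference),
            "n_features": int(self.n_features),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "ReferenceStats":
        d = json.loads(Path(path).read_text())
        return cls(
            mean=np.asarray(d["mean"]),
            sd=np.asarray(d["sd"]),
            n_reference=d["n_reference"],
            reference_cohort=d["reference_cohort"],
        )


def embed_tiles(
    tiles: Sequence,
    embedder: Callable[[np.ndarray], np.ndarray],
    patient_ids: Sequence[str] | None = None,
    cohorts: Sequence[str] | None = None,
    tile_ids: Sequence[str] | None = None,
) -> TileFeatureTable:
    """Run a pluggable embedder over tiles and collect a feature table.

    ``tiles`` may be :class:`~ihcstrat.stain.Tile` objects (pixel array under
    ``.pixels``) or plain RGB arrays. The embedder must return a fixed-length
    1-D vector; a declared ``embedder.dim`` is checked when present.
    """
    n = len(tiles)
    if n == 0:
        raise ValueError("no tiles to embed")
    declared = getattr(embedder, "dim", None)
    vecs = []
    for t in tiles:
        pixels = getattr(t, "pixels", t)
        v = np.asarray(embedder(pixels), float).ravel()
        if declared is not None and v.size != declared:
            raise ValueError(f"embedder returned {v.size} features, declared {declared}")
        if vecs and v.size != vecs[0].size:
            raise ValueError("embedder dimension mismatch across tiles")
        vecs.append(v)
    if patient_ids is None:
        patient_ids = [getattr(t, "slide_id", f"P{i:04d}") for i, t in enumerate(tiles)]
    if cohorts is None:
        cohorts = ["unknown"] * n
    if tile_ids is None:
        tile_ids = [f"tile-{i:06d}" for i in range(n)]
    return TileFeatureTable.from_arrays(patient_ids, cohorts, tile_ids, np.vstack(vecs))


def compute_reference_stats(
    table: TileFeatureTable,
    reference_cohort: str,
    patient_weighted: bool = False,
) -> ReferenceStats:
    """Per-feature mean and sample sd over the reference cohort's tiles.

    With ``patient_weighted=True`` the statistics are computed over
    per-patient mean vectors instead of pooled tiles (exposed because the
    pooling level is an analysis choice; tile-level pooling is the default).
    Zero-variance features get their sd floored at a small epsilon, with a
    warning, so normalization never divides by zero.
    """
    ref = table.subset_cohort(reference_cohort)
    X = ref.X
    if patient_weighted:
        X = (
            ref.frame.groupby("patient_id")[ref.feature_columns]
            .mean()
            .to_numpy(float)
        )
    if X.shape[0] < 2:
        raise ValueError("need at least 2 reference rows to estimate an sd")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    n_zero = int(np.sum(sd < SD_FLOOR))
    if n_zero:
        warnings.warn(
            f"{n_zero} zero-variance feature(s); sd floored at {SD_FLOOR:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        sd = np.maximum(sd, SD_FLOOR)
    return ReferenceStats(
        mean=mean, sd=sd, n_reference=X.shape[0], reference_cohort=reference_cohort
    )


def apply_reference_norm(table: TileFeatureTable, stats: ReferenceStats) -> TileFeatureTable:
    """Standardize every row (all cohorts) by the reference statistics.

    The transform is the exact affine map (x - mean) / sd; it recenters and
    rescales by the reference only, so the non-reference cohort keeps its
    batch offset expressed in units of reference sd.
    """
    if stats.n_features != table.n_features:
        raise ValueError(
            f"stats have {stats.n_features} features, table has {table.n_features}"
        )
    out = table.frame.copy()
    out[table.feature_columns] = (table.X - stats.mean) / stats.sd
    return TileFeatureTable(out)
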
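"""Fixed-micron tiling of annotated regions and Macenko stain normalization.

Tiles are cut on a non-overlapping axis-aligned grid anchored at the
annotation's bounding-box top-left corner; a grid cell becomes a tile iff
the fraction of its area inside the polygon reaches ``coverage_min``
(exact polygon/square intersection via shapely).

Stain handling follows the Macenko procedure: convert tissue pixels to
optical density, take the two leading right-singular directions of the OD
cloud, locate the extreme (alpha / 100-alpha percentile) angle directions in
that plane, and use them as the absorbance directions of the two chromogens
(hematoxylin-like counterstain and DAB-like chromogen). Normalization
re-expresses a tile's least-squares stain concentrations in a reference
stain basis, after per-stain rescaling by robust (99th percentile) maximum
concentrations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from shapely.geometry import Polygon, box, shape, mapping

__all__ = [
    "RegionAnnotation",
    "Tile",
    "StainModel",
    "InsufficientTissueError",
    "DegenerateStainError",
    "extract_tiles",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_matrix",
    "normalize_tile",
    "read_annotations",
    "write_annotations",
]

OD_EPS = 1e-6  # guards log(0); small enough that OD(io/e) = 1 to ~1e-8


class InsufficientTissueError(ValueError):
    """Raised when a tile has too few above-threshold (tissue) pixels."""


class DegenerateStainError(ValueError):
    """Raised when the OD cloud is rank-deficient (effectively one stain)."""


@dataclass
class RegionAnnotation:
    """A manually selected tumor-area polygon, vertices in microns."""

    slide_id: str
    polygon: Sequence[tuple[float, float]]
    label: str = "tumor"

    def __post_init__(self) -> None:
        pts = [tuple(map(float, p)) for p in self.polygon]
        if len(pts) >= 2 and pts[0] == pts[-1]:
            pts = pts[:-1]  # drop explicit closure
        if len(pts) < 3:
            raise ValueError("polygon needs at least 3 distinct vertices")
        poly = Polygon(pts)
        if not poly.is_valid:
            raise ValueError("polygon is self-intersecting or otherwise invalid")
        if poly.area <= 0:
            raise ValueError("degenerate polygon with zero area")
        self.polygon = pts

    def as_shapely(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass
class Tile:
    """A square image patch of fixed physical size."""

    slide_id: str
    origin: tuple[float, float]  # microns
    size_um: float
    pixels: np.ndarray
    mpp: float

    def __post_init__(self) -> None:
        side = int(round(self.size_um / self.mpp))
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[0] != side or p.shape[1] != side or p.shape[2] != 3:
            raise ValueError(
                f"pixel array must be {side}x{side}x3 for size_um={self.size_um}, mpp={self.mpp}"
            )
        if p.min() < 0 or p.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        self.pixels = p


@dataclass
class StainModel:
    """Macenko output: 3x2 column-unit-norm stain matrix + robust max concentrations."""

    stain_matrix: np.ndarray
    max_concentrations: np.ndarray
    io: float = 255.0
    beta: float = 0.15
    alpha: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.stain_matrix, float)
        if m.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        norms = np.linalg.norm(m, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("stain matrix columns must be unit-norm")
        c = np.asarray(self.max_concentrations, float)
        if c.shape != (2,) or np.any(c <= 0):
            raise ValueError("max_concentrations must be 2 positive reals")
        self.stain_matrix = m
        self.max_concentrations = c

    def to_json(self, path=None):
        payload = {
            "stain_matrix": self.stain_matrix.tolist(),
            "max_concentrations": self.max_concentrations.tolist(),
            "io": self.io,
            "beta": self.beta,
            "alpha": self.alpha,
        }
        if path is None:
            return json.dumps(payload)
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, source) -> "StainModel":
        if isinstance(source, (str, Path)) and Path(source).exists():
            d = json.loads(Path(source).read_text())
        else:
            d = json.loads(source)
        return cls(
            stain_matrix=np.asarray(d["stain_matrix"]),
            max_concentrations=np.asarray(d["max_concentrations"]),
            io=d["io"],
            beta=d["beta"],
            alpha=d["alpha"],
        )


# ---------------------------------------------------------------------------
# optical density
# ---------------------------------------------------------------------------

def rgb_to_od(pixels: np.ndarray, io: float = 255.0) -> np.ndarray:
    """Optical density: OD = -log((I + eps) / io)."""
    if io <= 0:
        raise ValueError("io must be positive")
    arr = np.asarray(pixels, float)
    return -np.log((arr + OD_EPS) / io)


def od_to_rgb(od: np.ndarray, io: float = 255.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, rounded to integers in [0, io]."""
    if io <= 0:
        raise ValueError("io must be positive")
    arr = io * np.exp(-np.asarray(od, float)) - OD_EPS
    out = np.rint(arr).clip(0, io)
    return out.astype(np.uint8 if io <= 255 else np.uint16)


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def extract_tiles(
    region: RegionAnnotation,
    image: np.ndarray | Callable[[int, int, int], np.ndarray | None],
    mpp: float,
    size_um: float = 100.0,
    coverage_min: float = 0.5,
) -> list[Tile]:
    """Cut ``size_um``-square tiles from the region's bounding-box grid.

    ``image`` is either a full raster (H x W x 3, pixel (0,0) at micron
    origin (0,0)) or an accessor callable ``(x_px, y_px, side) -> array``
    returning ``None`` when the window is unavailable. Grid cells whose
    polygon coverage falls below ``coverage_min`` are dropped, as are cells
    whose pixel window leaves the raster.
    """
    if mpp is None or mpp <= 0:
        raise ValueError("mpp must be a positive real")
    if size_um <= 0:
        raise ValueError("size_um must be positive")
    poly = region.as_shapely()
    minx, miny, maxx, maxy = poly.bounds
    nx = max(1, math.ceil((maxx - minx) / size_um - 1e-9))
    ny = max(1, math.ceil((maxy - miny) / size_um - 1e-9))
    side = int(round(size_um / mpp))
    cell_area = size_um * size_um

    if callable(image):
        accessor = image
    else:
        raster = np.asarray(image)

        def accessor(x_px: int, y_px: int, s: int):
            if x_px < 0 or y_px < 0 or y_px + s > raster.shape[0] or x_px + s > raster.shape[1]:
                return None
            return raster[y_px : y_px + s, x_px : x_px + s]

    tiles: list[Tile] = []
    for j in range(ny):
        for i in range(nx):
            x = minx + i * size_um
            y = miny + j * size_um
            cell = box(x, y, x + size_um, y + size_um)
            coverage = poly.intersection(cell).area / cell_area
            if coverage + 1e-12 < coverage_min:
                continue
            x_px = int(round(x / mpp))
            y_px = int(round(y / mpp))
            pix = accessor(x_px, y_px, side)
            if pix is None:
                continue
            tiles.append(
                Tile(
                    slide_id=region.slide_id,
                    origin=(x, y),
                    size_um=size_um,
                    pixels=np.asarray(pix).copy(),
                    mpp=mpp,
                )
            )
    return tiles


# ---------------------------------------------------------------------------
# Macenko stain estimation
# ---------------------------------------------------------------------------

def _tissue_od(pixels: np.ndarray, io: float, beta: float) -> np.ndarray:
    od = rgb_to_od(pixels, io).reshape(-1, 3)
    return od[np.all(od >= beta, axis=1)]


def estimate_stain_matrix(
    tile,
    beta: float = 0.15,
    alpha: float = 1.0,
    io: float = 255.0,
    min_tissue: int = 50,
    degenerate_tol: float = 0.02,
) -> StainModel:
    """Macenko stain-vector estimation on one tile (or pooled pixel array).

    Accepts a :class:`Tile`, an RGB array, or a list of tiles/arrays whose
    pixels are pooled (per-slide estimation). Raises
    :class:`InsufficientTissueError` when fewer than ``min_tissue`` pixels
    exceed the OD threshold, and :class:`DegenerateStainError` when the
    second singular direction carries less than ``degenerate_tol`` of the
    first's energy (single-stain tile).
    """
    if isinstance(tile, (list, tuple)):
        parts = [_tissue_od(getattr(t, "pixels", t), io, beta) for t in tile]
        od = np.vstack(parts) if parts else np.empty((0, 3))
    else:
        od = _tissue_od(getattr(tile, "pixels", tile), io, beta)
    if od.shape[0] < min_tissue:
        raise InsufficientTissueError(
            f"only {od.shape[0]} tissue pixels above OD {beta}; need {min_tissue}"
        )
    # leading plane of the OD cloud
    _, s, vt = np.linalg.svd(od, full_matrices=False)
    if s[1] / s[0] < degenerate_tol:
        raise DegenerateStainError(
            "OD cloud is effectively rank-1 (a single stain); cannot separate two stains"
        )
    basis = vt[:2].T  # 3 x 2
    for jcol in range(2):  # orient so projections are mostly positive
        if basis[:, jcol].sum() < 0:
            basis[:, jcol] = -basis[:, jcol]
    proj = od @ basis
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [alpha, 100.0 - alpha])
    cols = []
    for ang in (lo, hi):
        v = basis @ np.array([np.cos(ang), np.sin(ang)])
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)  # nonnegative absorbance
        nrm = np.linalg.norm(v)
        if nrm < 1e-12:
            raise DegenerateStainError("extreme-angle direction collapsed to zero")
        cols.append(v / nrm)
    # column 1 = hematoxylin-like (larger red-channel absorbance)
    if cols[0][0] < cols[1][0]:
        cols = [cols[1], cols[0]]
    m = np.column_stack(cols)
    if np.linalg.norm(m[:, 0] - m[:, 1]) < 1e-3:
        raise DegenerateStainError("both stain directions coincide")
    conc, *_ = np.linalg.lstsq(m, od.T, rcond=None)
    conc = np.clip(conc, 0.0, None)
    max_c = np.maximum(np.percentile(conc, 99.0, axis=1), 1e-6)
    return StainModel(stain_matrix=m, max_concentrations=max_c, io=io, beta=beta, alpha=alpha)


def normalize_tile(tile, source: StainModel, reference: StainModel):
    """Remap a tile's colors onto the reference stain basis.

    Concentrations are solved from OD = M_source @ C by least squares,
    clipped at zero, rescaled per stain by the ratio of reference to source
    robust maxima, and re-rendered with the reference matrix. Returns the
    same kind of object it was given (Tile in, Tile out).
    """
    cond = np.linalg.cond(source.stain_matrix)
    if cond > 1e6:
        raise ValueError(f"source stain matrix ill-conditioned (cond={cond:.3g})")
    pixels = getattr(tile, "pixels", tile)
    shp = np.asarray(pixels).shape
    od = rgb_to_od(pixels, source.io).reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(source.stain_matrix, od.T, rcond=None)
    conc = np.clip(conc, 0.0, None)
    scale = reference.max_concentrations / source.max_concentrations
    od_new = (reference.stain_matrix @ (conc * scale[:, None])).T
    out = od_to_rgb(od_new, reference.io).reshape(shp)
    if hasattr(tile, "pixels"):
        return Tile(
            slide_id=tile.slide_id,
            origin=tile.origin,
            size_um=tile.size_um,
            pixels=out,
            mpp=tile.mpp,
        )
    return out


# ---------------------------------------------------------------------------
# annotation IO (GeoJSON, coordinates in microns)
# ---------------------------------------------------------------------------

def read_annotations(path) -> list[RegionAnnotation]:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    regions = []
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise ValueError(f"unsupported geometry {geom.geom_type}")
        props = feat.get("properties") or {}
        regions.append(
            RegionAnnotation(
                slide_id=str(props.get("slide_id", "slide")),
                polygon=list(geom.exterior.coords),
                label=str(props.get("label", "tumor")),
            )
        )
    return regions


def write_annotations(regions: Sequence[RegionAnnotation], path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(r.as_shapely()),
            "properties": {"slide_id": r.slide_id, "label": r.label},
        }
        for r in regions
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
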
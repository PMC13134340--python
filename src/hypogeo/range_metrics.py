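"""Geographic range geometry: equal-area projection, AOO, EOO.

IUCN Criterion B scores a taxon's range with two areas:

* **AOO** (area of occupancy, B2): the summed area of occupied 2 km × 2 km
  grid cells, optionally rescaled by a correction factor when the sampling
  grain is coarser than the 2-km reference grid.
* **EOO** (extent of occurrence, B1): the area of the smallest boundary
  drawn around all occurrences — here the alpha shape of the occurrence
  points, which at ``alpha = 0`` is the convex hull.

Occurrence coordinates arrive as WGS84 latitude/longitude and are projected
onto a plane with a Lambert azimuthal equal-area (LAEA) projection centred
on the occurrence centroid, so planar areas in km² are faithful to the
spherical areas they represent.  EOO for fewer than three distinct points
is undefined (a hull needs three non-collinear points); exactly-collinear
point sets get a zero area with a degeneracy flag so downstream policy can
decide what to do with them.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay
from shapely.geometry import MultiPoint, Polygon, box
from shapely.ops import unary_union

__all__ = [
    "EARTH_RADIUS_KM",
    "EooStatus",
    "OccurrenceSet",
    "RangeMetrics",
    "project_points",
    "inverse_project",
    "compute_aoo",
    "compute_eoo",
    "range_metrics_for",
    "range_geojson",
]

#: IUGG mean Earth radius, km (authalic sphere).
EARTH_RADIUS_KM = 6371.0088

#: Resolution used to deduplicate planar coordinates before EOO (1 m in km).
DEDUP_KM = 1e-3


class EooStatus(enum.Enum):
    OK = "OK"
    UNDEFINED_TOO_FEW_POINTS = "UNDEFINED_TOO_FEW_POINTS"
    DEGENERATE_COLLINEAR = "DEGENERATE_COLLINEAR"


@dataclass
class OccurrenceSet:
    """Occurrence localities of one phylotype, geographic and planar."""

    phylotype_id: str
    points_geo: list[tuple[float, float]]  # (lat, lon) decimal degrees
    points_planar: np.ndarray | None = None  # (n, 2) in km, set by project()
    center: tuple[float, float] | None = None  # projection centre (lat, lon)

    def project(self) -> "OccurrenceSet":
        self.points_planar, self.center = project_points(self.points_geo, return_center=True)
        return self

    @property
    def n_unique(self) -> int:
        if self.points_planar is None:
            raise ValueError("project() before counting unique planar points")
        return len(_dedup(self.points_planar))


@dataclass
class RangeMetrics:
    """AOO/EOO summary for one phylotype, with the parameters used."""

    phylotype_id: str
    aoo_km2: float
    n_occupied_cells: int
    eoo_km2: float | None
    eoo_status: EooStatus
    n_points: int
    n_unique: int
    cell_km: float = 2.0
    correction_factor: float = 1.0
    alpha: float = 0.0
    occupied_cells: list[tuple[int, int]] = field(default_factory=list, repr=False)
    hull: Polygon | None = field(default=None, repr=False)
    center: tuple[float, float] | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project_points(points_geo, center: tuple[float, float] | None = None,
                   return_center: bool = False):
    """Project (lat, lon) points to planar km with a spherical LAEA projection.

    The projection is centred on the mean latitude/longitude of the input
    unless ``center`` is given, so a single point maps to the origin and
    local distortion around the occurrence cloud is minimal.
    """
    pts = np.asarray(points_geo, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("cannot project an empty point set")
    if np.any(np.abs(pts[:, 0]) > 90) or np.any(np.abs(pts[:, 1]) > 180):
        raise ValueError("coordinates outside valid latitude/longitude range")
    if center is None:
        center = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
    lat0, lon0 = math.radians(center[0]), math.radians(center[1])
    lat = np.radians(pts[:, 0])
    dlon = np.radians(pts[:, 1]) - lon0
    cosc = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(dlon)
    cosc = np.clip(cosc, -1.0, 1.0)
    # k = sqrt(2 / (1 + cos c)); the antipode (cos c = -1) is a singularity
    with np.errstate(divide="ignore"):
        k = np.sqrt(2.0 / (1.0 + cosc))
    x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(dlon)
    y = EARTH_RADIUS_KM * k * (
        np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(dlon)
    )
    planar = np.column_stack([x, y])
    if return_center:
        return planar, center
    return planar


def inverse_project(points_planar, center: tuple[float, float]):
    """Inverse LAEA: planar km back to (lat, lon) degrees around ``center``."""
    pts = np.asarray(points_planar, dtype=float).reshape(-1, 2)
    lat0, lon0 = math.radians(center[0]), math.radians(center[1])
    rho = np.hypot(pts[:, 0], pts[:, 1])
    c = 2.0 * np.arcsin(np.clip(rho / (2.0 * EARTH_RADIUS_KM), -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        lat = np.arcsin(np.cos(c) * math.sin(lat0) + pts[:, 1] * np.sin(c) * math.cos(lat0) / rho)
        lon = lon0 + np.arctan2(
            pts[:, 0] * np.sin(c),
            rho * math.cos(lat0) * np.cos(c) - pts[:, 1] * math.sin(lat0) * np.sin(c),
        )
    at_origin = rho < 1e-12
    lat[at_origin] = lat0
    lon[at_origin] = lon0
    return np.degrees(np.column_stack([lat, lon]))


# ---------------------------------------------------------------------------
# AOO
# ---------------------------------------------------------------------------

def compute_aoo(points_planar, cell_km: float = 2.0,
                correction_factor: float = 1.0) -> tuple[float, int]:
    """Area of occupancy from grid-cell occupancy.

    Cells are half-open squares ``[i·c, (i+1)·c) × [j·c, (j+1)·c)`` anchored
    at the projection origin.  Returns ``(aoo_km2, n_occupied_cells)`` with
    ``aoo_km2 = n_cells × c² × correction_factor``.
    """
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    if correction_factor <= 0:
        raise ValueError("correction_factor must be positive")
    cells = occupied_cells(points_planar, cell_km)
    n = len(cells)
    return n * cell_km * cell_km * correction_factor, n


def occupied_cells(points_planar, cell_km: float = 2.0) -> set[tuple[int, int]]:
    pts = np.asarray(points_planar, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("empty point set")
    idx = np.floor(pts / cell_km).astype(np.int64)
    return {(int(i), int(j)) for i, j in idx}


# ---------------------------------------------------------------------------
# EOO
# ---------------------------------------------------------------------------

def _dedup(points_planar, resolution_km: float = DEDUP_KM) -> np.ndarray:
    """Drop points that coincide at ``resolution_km``; originals are kept
    (rounding is only the duplicate key, so areas are not perturbed)."""
    pts = np.asarray(points_planar, dtype=float).reshape(-1, 2)
    seen: set[tuple[int, int]] = set()
    keep = []
    for p in pts:
        key = (int(round(p[0] / resolution_km)), int(round(p[1] / resolution_km)))
        if key not in seen:
            seen.add(key)
            keep.append(p)
    return np.asarray(keep)


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    p0 = pts[0]
    d = pts - p0
    # cross product of the longest edge direction with every offset
    k = int(np.argmax(np.einsum("ij,ij->i", d, d)))
    v = d[k]
    norm = math.hypot(*v)
    if norm == 0:
        return True
    cross = np.abs(d[:, 0] * v[1] - d[:, 1] * v[0]) / norm
    return bool(np.all(cross < tol))


def compute_eoo(points_planar, alpha: float = 0.0) -> tuple[float | None, EooStatus]:
    """Extent of occurrence as the alpha-shape area of the planar points.

    ``alpha = 0`` gives the convex hull.  For ``alpha > 0`` the shape is the
    union of Delaunay triangles with circumradius < 1/alpha (the convention
    of the alphashape library), summed over components.  Points are
    deduplicated at 1 m before the geometry is built.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    pts = _dedup(points_planar)
    if len(pts) < 3:
        return None, EooStatus.UNDEFINED_TOO_FEW_POINTS
    if _collinear(pts):
        return 0.0, EooStatus.DEGENERATE_COLLINEAR
    if alpha == 0.0:
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        return float(hull.area), EooStatus.OK
    shape = alpha_shape(pts, alpha)
    return float(shape.area), EooStatus.OK


def alpha_shape(points: np.ndarray, alpha: float):
    """Alpha shape as the union of Delaunay triangles with circumradius < 1/alpha."""
    pts = np.asarray(points, dtype=float)
    tri = Delaunay(pts)
    keep = []
    limit = 1.0 / alpha
    for simplex in tri.simplices:
        a, b, c = pts[simplex]
        if _circumradius(a, b, c) < limit:
            keep.append(Polygon([a, b, c]))
    if not keep:
        return Polygon()
    return unary_union(keep)


def _circumradius(a, b, c) -> float:
    la = math.dist(b, c)
    lb = math.dist(a, c)
    lc = math.dist(a, b)
    area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
    if area2 == 0:
        return math.inf
    return la * lb * lc / (2.0 * area2)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def range_metrics_for(occ: OccurrenceSet, cell_km: float = 2.0,
                      correction_factor: float = 1.0, alpha: float = 0.0) -> RangeMetrics:
    """Full range-metric bundle for one occurrence set.

    AOO uses all points; EOO deduplicates coordinates first (replicate
    samples at one locality must not manufacture hull vertices).
    """
    if not occ.points_geo:
        raise ValueError(f"{occ.phylotype_id}: empty occurrence set")
    if occ.points_planar is None:
        occ.project()
    aoo, n_cells = compute_aoo(occ.points_planar, cell_km, correction_factor)
    eoo, status = compute_eoo(occ.points_planar, alpha)
    unique = _dedup(occ.points_planar)
    hull = None
    if status is EooStatus.OK and alpha == 0.0:
        hull = MultiPoint([tuple(p) for p in unique]).convex_hull
    elif status is EooStatus.OK:
        hull = alpha_shape(unique, alpha)
    return RangeMetrics(
        phylotype_id=occ.phylotype_id,
        aoo_km2=aoo,
        n_occupied_cells=n_cells,
        eoo_km2=eoo,
        eoo_status=status,
        n_points=len(occ.points_geo),
        n_unique=len(unique),
        cell_km=cell_km,
        correction_factor=correction_factor,
        alpha=alpha,
        occupied_cells=sorted(occupied_cells(occ.points_planar, cell_km)),
        hull=hull,
        center=occ.center,
    )


def range_geojson(metrics: RangeMetrics) -> dict:
    """GeoJSON FeatureCollection of hull polygon and occupied cells (WGS84).

    Intended for map QC; coordinates are inverse-projected back to
    longitude/latitude order as GeoJSON requires.
    """
    if metrics.center is None:
        raise ValueError("metrics lack a projection centre; build via range_metrics_for")
    features = []

    def ring_to_lonlat(coords):
        geo = inverse_project(np.asarray(coords), metrics.center)
        return [[round(float(lon), 6), round(float(lat), 6)] for lat, lon in geo]

    if metrics.hull is not None and not metrics.hull.is_empty and metrics.hull.geom_type == "Polygon":
        features.append({
            "type": "Feature",
            "properties": {"role": "eoo_hull", "phylotype": metrics.phylotype_id,
                           "eoo_km2": metrics.eoo_km2},
            "geometry": {"type": "Polygon",
                         "coordinates": [ring_to_lonlat(list(metrics.hull.exterior.coords))]},
        })
    c = metrics.cell_km
    for (i, j) in metrics.occupied_cells:
        cell = box(i * c, j * c, (i + 1) * c, (j + 1) * c)
        features.append({
            "type": "Feature",
            "properties": {"role": "aoo_cell", "phylotype": metrics.phylotype_id,
                           "cell": [i, j]},
            "geometry": {"type": "Polygon",
                         "coordinates": [ring_to_lonlat(list(cell.exterior.coords))]},
        })
    return {"type": "FeatureCollection", "features": features}
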
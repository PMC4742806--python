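"""Species range geometry: extent of occurrence and range masks.

A species' geographical range is summarised by the smallest convex polygon
(convex hull) containing its occurrence records; the extent of occurrence
(EOO) is the hull area minus any overlapping land.  All geometry is planar
Euclidean: coordinates are treated as lying in an equal-area plane, and
areas are converted to 10^6 km^2 via a constant scale factor.

Derived quantities:

* ``rel_margin_distance`` — 0 at the range margin, 1 halfway between the
  two farthest range endpoints, i.e. distance to the nearest hull edge
  divided by half the maximum endpoint separation (clipped to [0, 1]).
* ``within_range`` — point-in-hull mask; boundary points count as inside,
  so sampled margin locations are never dropped from permutation masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Point, Polygon

__all__ = [
    "RangeHull",
    "convex_hull_eoo",
    "rel_margin_distance",
    "within_range",
    "hull_to_geojson",
]

#: km^2 per square degree at the equator (111.195 km per degree, squared),
#: expressed in 10^6 km^2 so hull areas land on the EOO scale the trait
#: table uses.  Planar stand-in for an equal-area projection.
DEG2_TO_1E6KM2 = (111.195**2) / 1e6


class OutsideRangeError(ValueError):
    """Raised when a location outside the hull is passed where inside is required."""


@dataclass
class RangeHull:
    """Convex-hull range of one species.

    Attributes
    ----------
    species_id : str
        Identifier of the species the hull belongs to.
    vertices : np.ndarray, shape (k, 2)
        Ordered (lon, lat) vertices of the convex polygon (first vertex not
        repeated).  Empty for degenerate hulls.
    area : float
        Extent of occurrence in 10^6 km^2-equivalent units (hull area minus
        intersected land area, scaled by ``area_scale``).
    endpoints : np.ndarray, shape (2, 2)
        The farthest pair of input points.
    endpoint_separation : float
        Euclidean distance between the farthest endpoints, in coordinate units.
    degenerate : bool
        True when the input points do not span a polygon (point / collinear).
    """

    species_id: str
    vertices: np.ndarray
    area: float
    endpoints: np.ndarray
    endpoint_separation: float
    degenerate: bool = False
    polygon: Polygon | None = field(default=None, repr=False)

    def contains(self, lon: float, lat: float) -> bool:
        if self.polygon is None:
            return False
        return bool(self.polygon.covers(Point(lon, lat)))


def _farthest_pair(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Farthest pair among hull candidate points (brute force on hull vertices)."""
    if len(pts) == 1:
        return np.vstack([pts[0], pts[0]]), 0.0
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    return np.vstack([pts[i], pts[j]]), float(d[i, j])


def convex_hull_eoo(
    points: np.ndarray | Sequence[Sequence[float]],
    land_polygons: Iterable[Polygon] | None = None,
    species_id: str = "",
    area_scale: float = 1.0,
) -> RangeHull:
    """Convex hull of occurrence records and its land-corrected area.

    Parameters
    ----------
    points : array-like of shape (n, 2)
        (lon, lat) occurrence records; at least one point required, at least
        3 non-collinear points for a polygonal (non-degenerate) hull.
    land_polygons : iterable of shapely Polygon, optional
        Land masses whose intersection with the hull is subtracted from the
        EOO area.
    area_scale : float
        Multiplier converting squared coordinate units to the reporting unit
        (use :data:`DEG2_TO_1E6KM2` for degrees -> 10^6 km^2).

    Raises
    ------
    ValueError
        If no points are supplied.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("convex_hull_eoo requires at least one point")
    if pts.shape[1] != 2:
        raise ValueError(f"points must have shape (n, 2), got {pts.shape}")
    pts = pts[~np.isnan(pts).any(axis=1)]
    if len(pts) == 0:
        raise ValueError("all points are NaN")

    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    endpoints, sep = _farthest_pair(np.unique(pts, axis=0))

    if not isinstance(hull, Polygon):
        # point or line: zero-area degenerate hull
        return RangeHull(
            species_id=species_id,
            vertices=np.empty((0, 2)),
            area=0.0,
            endpoints=endpoints,
            endpoint_separation=sep,
            degenerate=True,
            polygon=None,
        )

    area = hull.area
    if land_polygons is not None:
        for land in land_polygons:
            area -= hull.intersection(land).area
    verts = np.asarray(hull.exterior.coords)[:-1]
    return RangeHull(
        species_id=species_id,
        vertices=verts,
        area=max(area, 0.0) * area_scale,
        endpoints=endpoints,
        endpoint_separation=sep,
        degenerate=False,
        polygon=hull,
    )


def rel_margin_distance(location: Sequence[float], hull: RangeHull) -> float:
    """Relative distance to the range margin, in [0, 1].

    0 exactly on the hull boundary; 1 at half the farthest-endpoint
    separation from the nearest edge (values beyond are clipped).

    Raises
    ------
    OutsideRangeError
        If the location falls outside the hull.
    """
    if hull.polygon is None:
        raise OutsideRangeError("degenerate hull has no interior")
    p = Point(float(location[0]), float(location[1]))
    if not hull.polygon.covers(p):
        raise OutsideRangeError(f"location {tuple(location)} is outside the range hull")
    if hull.endpoint_separation <= 0:
        return 0.0
    edge_dist = hull.polygon.exterior.distance(p)
    return float(np.clip(edge_dist / (hull.endpoint_separation / 2.0), 0.0, 1.0))


def within_range(locations, hull: RangeHull) -> np.ndarray:
    """Boolean mask of locations inside (or on the boundary of) the hull.

    ``locations`` may be a DataFrame with ``lon``/``lat`` columns or an
    (n, 2) array.  Degenerate hulls contain nothing.
    """
    if hasattr(locations, "columns"):
        lon = np.asarray(locations["lon"], dtype=float)
        lat = np.asarray(locations["lat"], dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(locations, dtype=float))
        lon, lat = arr[:, 0], arr[:, 1]
    if hull.polygon is None:
        return np.zeros(len(lon), dtype=bool)
    pts = shapely.points(lon, lat)
    return shapely.covers(hull.polygon, pts)


def hull_from_geojson(record: dict) -> RangeHull:
    """Rebuild a :class:`RangeHull` from its GeoJSON-style record."""
    props = record.get("properties", {})
    geom = record.get("geometry")
    if geom is None:
        return RangeHull(
            species_id=props.get("species_id", ""),
            vertices=np.empty((0, 2)),
            area=float(props.get("area", 0.0)),
            endpoints=np.zeros((2, 2)),
            endpoint_separation=float(props.get("endpoint_separation", 0.0)),
            degenerate=True,
            polygon=None,
        )
    ring = np.asarray(geom["coordinates"][0], dtype=float)
    poly = Polygon(ring)
    return RangeHull(
        species_id=props.get("species_id", ""),
        vertices=ring[:-1],
        area=float(props.get("area", poly.area)),
        endpoints=np.zeros((2, 2)),
        endpoint_separation=float(props.get("endpoint_separation", 0.0)),
        degenerate=False,
        polygon=poly,
    )


def hull_to_geojson(hull: RangeHull) -> dict:
    """GeoJSON-style Feature record for serialization in run directories."""
    if hull.degenerate or hull.polygon is None:
        geometry = None
    else:
        ring = np.vstack([hull.vertices, hull.vertices[:1]]).tolist()
        geometry = {"type": "Polygon", "coordinates": [ring]}
    return {
        "type": "Feature",
        "geometry": geometry,
        "properties": {
            "species_id": hull.species_id,
            "area": hull.area,
            "endpoint_separation": hull.endpoint_separation,
            "degenerate": hull.degenerate,
        },
    }
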
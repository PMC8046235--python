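"""Shared geospatial primitives: equal-area projection, raster container, GeoJSON I/O.

All vector geometries cross module boundaries in geographic lon/lat (WGS84).
Areas, grids and zonal statistics are computed in a global equal-area
projection — Mollweide on the authalic sphere by default — so that a square
metre is a square metre everywhere on the globe.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

#: Authalic Earth radius in metres (sphere with the same surface area as the
#: WGS84 ellipsoid); using it makes projected areas match spherical areas.
EARTH_RADIUS_M = 6_371_007.1809

KM2_PER_M2 = 1e-6

#: Densification step (degrees) applied before projecting, so long straight
#: edges in lon/lat stay area-faithful after the non-linear map.
_SEGMENTIZE_DEG = 0.05

# GeoTIFF tag ids used for minimal georeferencing.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922


# ---------------------------------------------------------------------------
# Mollweide projection (forward and inverse) on the authalic sphere
# ---------------------------------------------------------------------------

def _mollweide_theta(lat_rad: np.ndarray) -> np.ndarray:
    """Solve 2θ + sin 2θ = π sin φ by Newton iteration (vectorised)."""
    sin_lat = np.sin(lat_rad)
    theta = np.arcsin(np.clip(sin_lat, -1.0, 1.0))
    target = math.pi * sin_lat
    for _ in range(50):
        f = 2.0 * theta + np.sin(2.0 * theta) - target
        fp = 2.0 + 2.0 * np.cos(2.0 * theta)
        # At the poles fp -> 0; theta is already exact there.
        step = np.where(np.abs(fp) > 1e-12, f / np.maximum(fp, 1e-12), 0.0)
        theta = theta - step
        if np.max(np.abs(step)) < 1e-13:
            break
    return theta


def mollweide_forward(lon_deg: np.ndarray, lat_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat degrees to Mollweide x/y metres (central meridian 0)."""
    lon = np.deg2rad(np.asarray(lon_deg, dtype=float))
    lat = np.deg2rad(np.asarray(lat_deg, dtype=float))
    theta = _mollweide_theta(lat)
    x = (2.0 * math.sqrt(2.0) / math.pi) * EARTH_RADIUS_M * lon * np.cos(theta)
    y = math.sqrt(2.0) * EARTH_RADIUS_M * np.sin(theta)
    return x, y


def mollweide_inverse(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Invert :func:`mollweide_forward`; returns lon/lat in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    theta = np.arcsin(np.clip(y / (math.sqrt(2.0) * EARTH_RADIUS_M), -1.0, 1.0))
    lat = np.arcsin(np.clip((2.0 * theta + np.sin(2.0 * theta)) / math.pi, -1.0, 1.0))
    cos_theta = np.cos(theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        lon = math.pi * x / (2.0 * math.sqrt(2.0) * EARTH_RADIUS_M * cos_theta)
    lon = np.where(cos_theta < 1e-12, 0.0, lon)
    return np.rad2deg(lon), np.rad2deg(lat)


def to_equal_area(geom: BaseGeometry, densify: bool = True) -> BaseGeometry:
    """Map a lon/lat geometry into the equal-area plane (metres)."""
    if geom.is_empty:
        return geom
    if densify:
        geom = shapely.segmentize(geom, _SEGMENTIZE_DEG)

    def _fwd(coords: np.ndarray) -> np.ndarray:
        x, y = mollweide_forward(coords[:, 0], coords[:, 1])
        return np.column_stack([x, y])

    return shapely.transform(geom, _fwd)


def from_equal_area(geom: BaseGeometry) -> BaseGeometry:
    """Map an equal-area-plane geometry back to lon/lat degrees."""
    if geom.is_empty:
        return geom

    def _inv(coords: np.ndarray) -> np.ndarray:
        lon, lat = mollweide_inverse(coords[:, 0], coords[:, 1])
        return np.column_stack([lon, lat])

    return shapely.transform(geom, _inv)


def geodesic_area_km2(geom: BaseGeometry) -> float:
    """Area in km² of a lon/lat geometry, via the equal-area projection."""
    if geom.is_empty:
        return 0.0
    return to_equal_area(geom).area * KM2_PER_M2


def make_valid(geom: BaseGeometry) -> BaseGeometry:
    """Repair an invalid geometry, keeping only its areal component."""
    if geom.is_valid:
        return geom
    fixed = shapely.make_valid(geom)
    if fixed.geom_type in ("Polygon", "MultiPolygon"):
        return fixed
    # make_valid may emit a collection with stray lines/points: keep polygons.
    polys = [g for g in getattr(fixed, "geoms", [fixed]) if g.geom_type in ("Polygon", "MultiPolygon")]
    if not polys:
        return shapely.Polygon()
    return shapely.union_all(polys)


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------

def read_geojson(path: str | Path) -> list[tuple[BaseGeometry, dict]]:
    """Read a GeoJSON FeatureCollection as ``[(geometry, properties), ...]``.

    Per RFC 7946 GeoJSON coordinates are WGS84 lon/lat; coordinate ranges are
    validated on load.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except OSError as exc:
        raise IOError(f"cannot read vector file {path}: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    out: list[tuple[BaseGeometry, dict]] = []
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        minx, miny, maxx, maxy = geom.bounds
        if minx < -180.0 - 1e-6 or maxx > 180.0 + 1e-6 or miny < -90.0 - 1e-6 or maxy > 90.0 + 1e-6:
            raise ValueError(
                f"{path}: coordinates outside lon/lat bounds; GeoJSON must be WGS84"
            )
        out.append((geom, dict(feat.get("properties") or {})))
    return out


def write_geojson(path: str | Path, features: Iterable[tuple[BaseGeometry, dict]]) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


# ---------------------------------------------------------------------------
# Raster container and GeoTIFF I/O
# ---------------------------------------------------------------------------

@dataclass
class Raster:
    """A single-band north-up raster.

    Attributes
    ----------
    data:
        2-D array, row 0 at the top (northernmost).
    x0, y0:
        Coordinates of the *outer corner* of the top-left pixel.
    px, py:
        Pixel width and height (both positive; rows step downward in y).
    crs:
        ``"lonlat"`` (degrees) or ``"equal_area"`` (metres in the analysis
        projection).
    nodata:
        Sentinel marking pixels with no observation, or None.
    """

    data: np.ndarray
    x0: float
    y0: float
    px: float
    py: float
    crs: str = "equal_area"
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.crs not in ("lonlat", "equal_area"):
            raise ValueError(f"unknown raster crs {self.crs!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        nrow, ncol = self.data.shape
        return (self.x0, self.y0 - nrow * self.py, self.x0 + ncol * self.px, self.y0)

    def valid_mask(self) -> np.ndarray:
        mask = np.isfinite(self.data.astype(float))
        if self.nodata is not None:
            mask &= self.data != self.nodata
        return mask

    def pixel_centers(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0 + (np.asarray(cols) + 0.5) * self.px
        ys = self.y0 - (np.asarray(rows) + 0.5) * self.py
        return xs, ys

    def window(self, minx: float, miny: float, maxx: float, maxy: float) -> tuple[int, int, int, int]:
        """Row/col slice bounds (i0, i1, j0, j1) covering a bbox, clipped."""
        nrow, ncol = self.data.shape
        j0 = max(0, int(math.floor((minx - self.x0) / self.px)))
        j1 = min(ncol, int(math.ceil((maxx - self.x0) / self.px)))
        i0 = max(0, int(math.floor((self.y0 - maxy) / self.py)))
        i1 = min(nrow, int(math.ceil((self.y0 - miny) / self.py)))
        return i0, max(i0, i1), j0, max(j0, j1)

    def pixel_area_km2(self, rows: np.ndarray) -> np.ndarray:
        """Per-pixel ground area in km² for the given row indices."""
        rows = np.asarray(rows)
        if self.crs == "equal_area":
            return np.full(rows.shape, self.px * self.py * KM2_PER_M2, dtype=float)
        # lon/lat grid: width shrinks with cos(latitude of the pixel centre)
        lat = self.y0 - (rows + 0.5) * self.py
        w = np.deg2rad(self.px) * EARTH_RADIUS_M * np.cos(np.deg2rad(lat))
        h = np.deg2rad(self.py) * EARTH_RADIUS_M
        return w * h * KM2_PER_M2

    # -- GeoTIFF round-trip -------------------------------------------------

    def to_geotiff(self, path: str | Path) -> None:
        meta = json.dumps({"crs": self.crs, "nodata": self.nodata}, sort_keys=True)
        tifffile.imwrite(
            Path(path),
            self.data,
            description=meta,
            extratags=[
                (_TAG_PIXEL_SCALE, "d", 3, (self.px, self.py, 0.0)),
                (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, self.x0, self.y0, 0.0)),
            ],
        )

    @classmethod
    def from_geotiff(cls, path: str | Path) -> "Raster":
        with tifffile.TiffFile(Path(path)) as tif:
            page = tif.pages[0]
            data = page.asarray()
            tags = page.tags
            try:
                scale = tags[_TAG_PIXEL_SCALE].value
                tie = tags[_TAG_TIEPOINT].value
            except KeyError as exc:
                raise ValueError(f"{path}: missing GeoTIFF georeferencing tags") from exc
            meta: dict = {}
            if 270 in tags:
                try:
                    meta = json.loads(tags[270].value)
                except (TypeError, json.JSONDecodeError):
                    meta = {}
        return cls(
            data=data,
            x0=float(tie[3]),
            y0=float(tie[4]),
            px=float(scale[0]),
            py=float(scale[1]),
            crs=meta.get("crs", "equal_area"),
            nodata=meta.get("nodata"),
        )
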
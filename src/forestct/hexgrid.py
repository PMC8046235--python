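"""Equal-area hexagonal tessellation and per-cell species richness.

Species footprints are aggregated on a grid of equal-area, equal-shape
hexagons (target cell area 10 km² by default) restricted to a band around
the equator. The default backend lays a flat regular hexagonal tiling in
the global equal-area projection plane, so every cell has identical
projected (hence ground) area; an icosahedral discrete-global-grid backend
is a recognised-but-unimplemented alternative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry

from .geoutil import KM2_PER_M2, Raster, mollweide_inverse, to_equal_area
from .range_io import SpeciesFootprint

logger = logging.getLogger(__name__)

#: Interior-overlap tolerance: intersections smaller than this fraction of a
#: cell are treated as boundary touches, keeping counts tessellation-stable.
_MIN_OVERLAP_FRAC = 1e-9


@dataclass
class HexCell:
    cell_id: str
    geometry: Polygon  # equal-area plane, metres
    area_km2: float
    species_ids: set[str] = field(default_factory=set)
    has_restoration_potential: bool = False

    @property
    def species_count(self) -> int:
        return len(self.species_ids)


@dataclass
class HexGrid:
    cell_area_km2: float
    lat_limit_deg: float
    cells: list[HexCell]
    grid_backend: str = "projected_hex"

    def cell_frame(self) -> pd.DataFrame:
        """Per-cell table: id, centroid lon/lat, count, restoration flag."""
        rows = []
        for c in self.cells:
            cx, cy = c.geometry.centroid.x, c.geometry.centroid.y
            lon, lat = mollweide_inverse(np.array([cx]), np.array([cy]))
            rows.append({
                "cell_id": c.cell_id,
                "lon": float(lon[0]),
                "lat": float(lat[0]),
                "area_km2": c.area_km2,
                "species_count": c.species_count,
                "has_restoration_potential": c.has_restoration_potential,
            })
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.cell_frame().to_csv(path, index=False, float_format="%.6f")


def build_grid(cell_area_km2: float = 10.0, lat_limit_deg: float = 50.0,
               extent: BaseGeometry | tuple[float, float, float, float] | None = None,
               extent_crs: str = "equal_area",
               backend: str = "projected_hex") -> HexGrid:
    """Tile an extent with equal-area hexagons.

    Parameters
    ----------
    cell_area_km2:
        Target (and, in the projected backend, exact) area of each hexagon.
    lat_limit_deg:
        Cells whose centre lies poleward of this latitude are excluded.
    extent:
        Region to tile: a geometry or (minx, miny, maxx, maxy) tuple, either
        in the equal-area plane (metres, default) or lon/lat degrees
        (``extent_crs="lonlat"``).
    """
    if backend == "icosahedral_dgg":
        raise NotImplementedError(
            "icosahedral discrete-global-grid backend requires external DGG "
            "tooling; use the 'projected_hex' backend")
    if backend != "projected_hex":
        raise ValueError(f"unknown grid backend {backend!r}")
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")
    if extent is None:
        raise ValueError("an extent is required")
    if isinstance(extent, tuple):
        extent = shapely.box(*extent)
    if extent_crs == "lonlat":
        extent = to_equal_area(extent)
    elif extent_crs != "equal_area":
        raise ValueError(f"unknown extent_crs {extent_crs!r}")
    if extent.is_empty or extent.area <= 0:
        raise ValueError("extent is degenerate")

    # Flat-top regular hexagon with side s: area = (3√3/2) s².
    s = math.sqrt(cell_area_km2 / KM2_PER_M2 * 2.0 / (3.0 * math.sqrt(3.0)))
    dx = 1.5 * s                 # column spacing
    dy = math.sqrt(3.0) * s      # row spacing
    minx, miny, maxx, maxy = extent.bounds
    q0 = int(math.floor(minx / dx)) - 1
    q1 = int(math.ceil(maxx / dx)) + 1
    r0 = int(math.floor(miny / dy)) - 1
    r1 = int(math.ceil(maxy / dy)) + 1

    angles = np.deg2rad(np.arange(6) * 60.0)
    vx = s * np.cos(angles)
    vy = s * np.sin(angles)

    shapely.prepare(extent)
    cells: list[HexCell] = []
    for q in range(q0, q1 + 1):
        cx = q * dx
        yoff = 0.5 * dy if (q % 2) else 0.0
        for r in range(r0, r1 + 1):
            cy = r * dy + yoff
            hexagon = Polygon(np.column_stack([vx + cx, vy + cy]))
            if not shapely.intersects(extent, hexagon):
                continue
            _, lat = mollweide_inverse(np.array([cx]), np.array([cy]))
            if abs(float(lat[0])) > lat_limit_deg:
                continue
            cells.append(HexCell(
                cell_id=f"h{q}_{r}",
                geometry=hexagon,
                area_km2=hexagon.area * KM2_PER_M2,
            ))
    return HexGrid(cell_area_km2=cell_area_km2, lat_limit_deg=lat_limit_deg,
                   cells=cells, grid_backend=backend)


def count_species_per_cell(grid: HexGrid, footprints: Iterable[SpeciesFootprint]) -> HexGrid:
    """Record, per cell, the species whose footprint overlaps its interior.

    A species is counted in a cell only when the intersection has positive
    area — boundary touches do not count, so counts are stable under the
    tessellation's shared edges. Counting is cumulative: calling again with
    further footprints only adds species.
    """
    tree = shapely.STRtree([c.geometry for c in grid.cells])
    for fp in footprints:
        if fp.geometry.is_empty:
            continue
        geom_ea = to_equal_area(fp.geometry)
        for idx in tree.query(geom_ea):
            cell = grid.cells[idx]
            inter = cell.geometry.intersection(geom_ea)
            if inter.area > _MIN_OVERLAP_FRAC * cell.geometry.area:
                cell.species_ids.add(fp.species_id)
    return grid


def flag_restoration_cells(grid: HexGrid, restoration_raster: Raster,
                           positive_threshold: float = 0.0) -> HexGrid:
    """Mark cells containing at least one restorable pixel centre.

    A cell has restoration potential when ≥ 1 valid raster pixel with value
    above ``positive_threshold`` has its centre inside the cell. A raster in
    lon/lat is handled by mapping pixel centres into the equal-area plane.
    """
    valid = restoration_raster.valid_mask() & (
        restoration_raster.data.astype(float) > positive_threshold)
    rows, cols = np.nonzero(valid)
    if rows.size == 0:
        for cell in grid.cells:
            cell.has_restoration_potential = False
        return grid
    xs, ys = restoration_raster.pixel_centers(rows, cols)
    if restoration_raster.crs == "lonlat":
        from .geoutil import mollweide_forward
        xs, ys = mollweide_forward(xs, ys)
    pts = shapely.points(xs, ys)
    tree = shapely.STRtree(pts)
    any_hit = False
    for cell in grid.cells:
        idx = tree.query(cell.geometry, predicate="contains")
        cell.has_restoration_potential = len(idx) > 0
        any_hit = any_hit or cell.has_restoration_potential
    if not any_hit:
        logger.warning("restoration raster does not overlap the grid; all flags False")
    return grid
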
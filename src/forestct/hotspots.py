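"""Multi-species restoration hotspots and country-level area tabulation.

A hotspot cell has at least *k* overlapping candidate-species ranges and
nonzero forest-restoration potential. Hotspot area is tabulated per country
at each exact species-count level; a cell straddling a border contributes to
each country in proportion to the intersection area, which conserves total
area.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .geoutil import KM2_PER_M2, to_equal_area
from .hexgrid import HexCell, HexGrid

#: Country borders sharing an edge have tiny sliver intersections from
#: floating point; overlaps above this fraction of the smaller polygon are
#: treated as genuinely overlapping input.
_OVERLAP_TOL = 1e-9


@dataclass
class HotspotTable:
    """Per-country hotspot areas (km²) by species-count level."""

    areas: pd.DataFrame  # index: country name; columns: int levels

    @property
    def row_totals(self) -> pd.Series:
        return self.areas.sum(axis=1)

    @property
    def column_totals(self) -> pd.Series:
        return self.areas.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.areas.to_numpy().sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.areas.copy()
        out.columns = [f"area_{lvl}_species_km2" for lvl in self.areas.columns]
        out["total_km2"] = self.row_totals
        total = out.sum(axis=0)
        total.name = "Total"
        return pd.concat([out, total.to_frame().T])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="Country", float_format="%.1f")


def select_hotspot_cells(grid: HexGrid, min_species: int) -> list[HexCell]:
    """Cells with ≥ ``min_species`` overlapping ranges and restoration potential."""
    if min_species < 1:
        raise ValueError("min_species must be >= 1")
    return [c for c in grid.cells
            if c.species_count >= min_species and c.has_restoration_potential]


def _validate_countries(countries_ea: list[tuple[str, BaseGeometry]]) -> None:
    tree = shapely.STRtree([g for _, g in countries_ea])
    for i, (name_i, geom_i) in enumerate(countries_ea):
        for j in tree.query(geom_i, predicate="intersects"):
            if j <= i:
                continue
            name_j, geom_j = countries_ea[j]
            inter = geom_i.intersection(geom_j).area
            if inter > _OVERLAP_TOL * min(geom_i.area, geom_j.area):
                raise ValueError(f"country polygons overlap: {name_i!r} and {name_j!r}")


def tabulate_area_by_country(cells: Iterable[HexCell],
                             countries: Iterable[tuple[str, BaseGeometry]],
                             levels: Sequence[int],
                             collapse_top: bool = False) -> HotspotTable:
    """Apportion hotspot-cell areas to countries, binned by species count.

    Parameters
    ----------
    cells:
        Hotspot cells (equal-area-plane geometries) with species counts.
    countries:
        (name, lon/lat geometry) pairs; must be non-overlapping.
    levels:
        Exact species-count columns, e.g. ``[4, 5, 6]``. Counts above the
        highest level are dropped unless ``collapse_top`` folds them into it.
    """
    levels = sorted(levels)
    countries_ea = [(name, to_equal_area(geom)) for name, geom in countries]
    _validate_countries(countries_ea)
    tree = shapely.STRtree([g for _, g in countries_ea])

    names = [name for name, _ in countries_ea]
    table = pd.DataFrame(0.0, index=names, columns=levels)
    top = levels[-1] if levels else None
    for cell in cells:
        level = cell.species_count
        if level not in levels:
            if collapse_top and top is not None and level > top:
                level = top
            else:
                continue
        for j in tree.query(cell.geometry, predicate="intersects"):
            name, geom = countries_ea[j]
            inter = cell.geometry.intersection(geom).area * KM2_PER_M2
            if inter > 0:
                table.loc[name, level] += inter
    table = table.loc[table.sum(axis=1) > 0]
    return HotspotTable(areas=table)


def total_hotspot_area(table: HotspotTable) -> float:
    """Grand total hotspot area (km²): the sum over all level columns."""
    return float(table.column_totals.sum())
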
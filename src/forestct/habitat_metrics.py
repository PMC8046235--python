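"""Per-species habitat-quality metrics.

Three percentages characterise the quality of each candidate species' range:

* percent of the range currently under forest cover (1-km raster),
* percent of the range with forest-restoration potential (1-km raster),
* percent of the range inside protected areas (IUCN categories I–VI,
  dissolved so overlapping designations are not double counted).

A species is a *good candidate* for release under current conditions when
part of its range is protected, part is forested, and invasive-species
control is not among its recommended actions.

Raster percentages use pixel-centre zonal semantics: a pixel belongs to the
range if its centre falls inside the footprint (half-open convention,
origin at the raster's upper-left). Pixels flagged nodata are excluded from
the denominator; when too little of the range is covered by valid pixels
(default < 50%), the forest percentage is reported as missing — mirroring
satellite-derived forest layers that skip small oceanic islands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .geoutil import Raster, from_equal_area, to_equal_area
from .range_io import SpeciesFootprint
from .species_catalog import SpeciesRecord

#: WDPA-style category labels counting as protected (IUCN I–VI).
PROTECTED_CATEGORIES = frozenset({"I", "Ia", "Ib", "II", "III", "IV", "V", "VI"})


@dataclass
class HabitatMetrics:
    species_id: str
    pct_forest_cover: float | None  # None = missing (insufficient raster coverage)
    pct_restoration: float
    pct_protected: float
    forest_data_coverage: float  # fraction of range overlapped by valid forest pixels
    good_candidate: bool = False


def percent_raster_overlap(footprint: SpeciesFootprint, raster: Raster,
                           positive_threshold: float = 0.0) -> tuple[float | None, float]:
    """Percent of a footprint covered by above-threshold raster pixels.

    Returns ``(percentage, data_coverage)`` where *percentage* is
    ``100 × area(positive valid pixels in range) / area(valid pixels in
    range)`` (None when no valid pixel centre falls in the range) and
    *data_coverage* is the valid-pixel area divided by the footprint area.
    """
    if footprint.geometry.is_empty or footprint.area_km2 <= 0:
        raise ValueError(f"empty footprint for species {footprint.species_id!r}")
    geom = footprint.geometry if raster.crs == "lonlat" else to_equal_area(footprint.geometry)
    i0, i1, j0, j1 = raster.window(*geom.bounds)
    if i1 <= i0 or j1 <= j0:
        return None, 0.0
    rows, cols = np.mgrid[i0:i1, j0:j1]
    rows, cols = rows.ravel(), cols.ravel()
    xs, ys = raster.pixel_centers(rows, cols)
    shapely.prepare(geom)
    inside = shapely.contains_xy(geom, xs, ys)
    if not inside.any():
        return None, 0.0
    rows, cols = rows[inside], cols[inside]
    values = raster.data[rows, cols]
    valid = raster.valid_mask()[rows, cols]
    weights = raster.pixel_area_km2(rows)
    valid_area = float(weights[valid].sum())
    data_coverage = valid_area / footprint.area_km2
    if valid_area == 0.0:
        return None, 0.0
    positive = valid & (values.astype(float) > positive_threshold)
    pct = 100.0 * float(weights[positive].sum()) / valid_area
    return pct, data_coverage


def percent_protected(footprint: SpeciesFootprint,
                      protected_areas: Iterable[tuple[BaseGeometry, str]]) -> float:
    """Percent of a footprint inside IUCN category I–VI protected areas.

    ``protected_areas`` is an iterable of (lon/lat geometry, category label)
    pairs. Polygons outside categories I–VI are ignored; the remainder are
    dissolved before intersecting, so stacked designations count once.
    """
    if footprint.geometry.is_empty or footprint.area_km2 <= 0:
        raise ValueError(f"empty footprint for species {footprint.species_id!r}")
    keep = [geom for geom, cat in protected_areas if str(cat).strip() in PROTECTED_CATEGORIES]
    if not keep:
        return 0.0
    union_ea = to_equal_area(shapely.union_all(keep))
    fp_ea = to_equal_area(footprint.geometry)
    inter = fp_ea.intersection(union_ea)
    return 100.0 * inter.area / fp_ea.area


def good_candidate(metrics: HabitatMetrics, record: SpeciesRecord,
                   min_protected_pct: float = 0.0, min_forest_pct: float = 0.0) -> bool:
    """Part of the range protected, some forest present, no invasive risk."""
    return (
        metrics.pct_protected > min_protected_pct
        and metrics.pct_forest_cover is not None
        and metrics.pct_forest_cover > min_forest_pct
        and "invasive_species_control" not in record.actions_recommended
    )


def compute_metrics(footprint: SpeciesFootprint, record: SpeciesRecord,
                    forest_raster: Raster, restoration_raster: Raster,
                    protected_areas: Iterable[tuple[BaseGeometry, str]],
                    forest_threshold: float = 0.0,
                    min_forest_coverage: float = 0.5) -> HabitatMetrics:
    """All habitat metrics for one species.

    ``forest_threshold`` is the canopy value above which a pixel counts as
    forest (0 accepts both binary extent layers and continuous percent-cover
    layers); ``min_forest_coverage`` is the fraction of the range that must
    be covered by valid forest pixels before a forest percentage is reported.
    """
    pct_forest, coverage = percent_raster_overlap(footprint, forest_raster, forest_threshold)
    if coverage < min_forest_coverage:
        pct_forest = None
    pct_rest, _ = percent_raster_overlap(footprint, restoration_raster, 0.0)
    metrics = HabitatMetrics(
        species_id=footprint.species_id,
        pct_forest_cover=pct_forest,
        pct_restoration=pct_rest if pct_rest is not None else 0.0,
        pct_protected=percent_protected(footprint, protected_areas),
        forest_data_coverage=coverage,
    )
    metrics.good_candidate = good_candidate(metrics, record)
    return metrics


def metrics_to_frame(metrics: Iterable[HabitatMetrics]) -> pd.DataFrame:
    rows = [{
        "species_id": m.species_id,
        "pct_forest_cover": np.nan if m.pct_forest_cover is None else m.pct_forest_cover,
        "pct_restoration": m.pct_restoration,
        "pct_protected": m.pct_protected,
        "forest_data_coverage": m.forest_data_coverage,
        "good_candidate": m.good_candidate,
    } for m in metrics]
    return pd.DataFrame(rows)
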
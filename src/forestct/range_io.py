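"""Species range polygons: attributed loading, presence/origin/seasonal
filtering, and per-species dissolved footprints clipped to the latitude band.

Range features carry the IUCN mapping-standard attributes:

* presence — 1 extant, 2 probably extant, 5 extinct, 6 presence uncertain
* origin   — 1 native, 2 reintroduced
* seasonal — 4 passage

The assessment keeps extant/probably-extant, native-or-reintroduced,
non-passage portions of a range (for Extinct-in-the-Wild species the
*extinct* portions, presence 5, are kept instead, since those delimit the
historical range a reintroduction would target). The retained features are
dissolved into one footprint per species and clipped to a band around the
equator (|lat| ≤ 50° by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import shapely
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .geoutil import geodesic_area_km2, make_valid, read_geojson

#: Attribute-code table (IUCN mapping standard); override via the
#: ``codes`` argument of :func:`filter_range_features`.
DEFAULT_CODES = {
    "presence_extant": (1, 2),
    "presence_extinct": (5,),
    "presence_uncertain": (6,),
    "origin_keep": (1, 2),
    "seasonal_passage": (4,),
}

DEFAULT_FIELD_MAP = {
    "species_id": "species_id",
    "presence": "presence",
    "origin": "origin",
    "seasonal": "seasonal",
}


@dataclass(frozen=True)
class RangeFeature:
    species_id: str
    geometry: BaseGeometry  # lon/lat (WGS84), valid
    presence_code: int
    origin_code: int
    seasonal_code: int


@dataclass
class SpeciesFootprint:
    """Dissolved, latitude-clipped range of one species."""

    species_id: str
    geometry: BaseGeometry  # lon/lat multipolygon (possibly empty)
    area_km2: float
    n_features_retained: int
    n_features_dropped: int


def load_range_features(path: str | Path, species_id: str | None = None,
                        field_map: Mapping[str, str] | None = None) -> list[RangeFeature]:
    """Load attributed range polygons from a GeoJSON file.

    Geometries are repaired to validity (make-valid); features whose repaired
    geometry is empty are retained with an empty geometry and dropped later
    during dissolve. ``species_id=None`` loads all species in the file.
    """
    fields = dict(DEFAULT_FIELD_MAP)
    fields.update(field_map or {})
    out: list[RangeFeature] = []
    for geom, props in read_geojson(path):
        for key in ("species_id", "presence", "origin", "seasonal"):
            if fields[key] not in props:
                raise KeyError(f"{path}: feature missing attribute {fields[key]!r}")
        sid = str(props[fields["species_id"]])
        if species_id is not None and sid != species_id:
            continue
        out.append(RangeFeature(
            species_id=sid,
            geometry=make_valid(geom),
            presence_code=int(props[fields["presence"]]),
            origin_code=int(props[fields["origin"]]),
            seasonal_code=int(props[fields["seasonal"]]),
        ))
    return out


def filter_range_features(features: Iterable[RangeFeature], extinct_in_wild: bool = False,
                          codes: Mapping[str, tuple[int, ...]] | None = None) -> list[RangeFeature]:
    """Apply the presence/origin/seasonal retention rule.

    For ordinary species keep presence ∈ {extant, probably extant}; for
    Extinct-in-the-Wild species keep presence ∈ {extinct}. In both cases the
    origin must be native or reintroduced, passage portions are dropped, and
    presence-uncertain portions are dropped.
    """
    table = dict(DEFAULT_CODES)
    table.update(codes or {})
    keep_presence = set(table["presence_extinct"] if extinct_in_wild else table["presence_extant"])
    keep_presence -= set(table["presence_uncertain"])
    origin_keep = set(table["origin_keep"])
    passage = set(table["seasonal_passage"])
    return [
        f for f in features
        if f.presence_code in keep_presence
        and f.origin_code in origin_keep
        and f.seasonal_code not in passage
    ]


def dissolve_and_clip(features: Iterable[RangeFeature], species_id: str | None = None,
                      lat_limit_deg: float = 50.0) -> SpeciesFootprint:
    """Union the retained features and clip to |lat| ≤ ``lat_limit_deg``.

    An empty input yields an empty footprint with zero area (not an error).
    Features with empty (unrepairable) geometry count as dropped.
    """
    feats = list(features)
    if species_id is None:
        ids = {f.species_id for f in feats}
        if len(ids) > 1:
            raise ValueError(f"features span multiple species: {sorted(ids)}")
        species_id = next(iter(ids)) if ids else ""
    geoms = [f.geometry for f in feats if not f.geometry.is_empty]
    n_dropped = len(feats) - len(geoms)
    if geoms:
        merged = shapely.union_all(geoms)
        band = box(-180.0, -lat_limit_deg, 180.0, lat_limit_deg)
        merged = merged.intersection(band)
    else:
        merged = shapely.Polygon()
    return SpeciesFootprint(
        species_id=species_id,
        geometry=merged,
        area_km2=geodesic_area_km2(merged),
        n_features_retained=len(geoms),
        n_features_dropped=n_dropped,
    )
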
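"""Synthetic scenario generation with stored ground truth.

Real inputs to the assessment (Red List range downloads, satellite forest
layers, the protected-area database) cannot be redistributed, so every
pipeline stage is exercised on generated landscapes whose true per-species
forest fraction, restoration fraction, protection fraction, multi-species
overlap structure and CT-category/action association are known exactly.

Two entry points:

* :func:`generate_scenario` — a full geometric scenario: a landmass, disk
  ranges (mostly disjoint, plus one engineered overlap cluster), 1-km
  forest and restoration rasters whose per-range fractions hit the targets
  to within one pixel, protected-area polygons hitting target protection
  fractions, and a Voronoi partition into countries.
* :func:`paper_margin_fixture` — an attribute-only catalog-and-metrics
  fixture that reproduces the published marginal counts of the 152-species
  assessment exactly (class × status table, 115/37 CT split, action
  recommendation cells, the 67-species composite, protected-percentage
  medians 7.4/0.9, missing-forest pattern).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Point, box
from shapely.geometry.base import BaseGeometry
from shapely.ops import voronoi_diagram

from .geoutil import KM2_PER_M2, Raster, from_equal_area, to_equal_area, write_geojson
from .range_io import RangeFeature
from .species_catalog import SpeciesRecord, write_catalog_csv


class InfeasibleScenarioError(ValueError):
    """The requested scenario parameters cannot be realised."""


@dataclass
class ScenarioParams:
    """Generator configuration (fractions in [0, 1], sizes in km/km²)."""

    n_species: int = 20
    #: landmass bounding box in lon/lat degrees (near the equator so a
    #: degree is ≈ 111 km)
    lon_min: float = 0.0
    lat_min: float = -1.5
    lon_max: float = 3.0
    lat_max: float = 1.5
    pixel_km: float = 1.0
    range_area_km2: tuple[float, float] = (800.0, 2500.0)
    forest_fractions: Sequence[float] | None = None
    restoration_fractions: Sequence[float] | None = None
    protection_fractions: Sequence[float] | None = None
    benign_fraction: float = 37 / 152
    p_invasive_benign: float = 24 / 37
    p_invasive_reintro: float = 47 / 115
    p_restoration_benign: float = 10 / 37
    p_restoration_reintro: float = 53 / 115
    n_countries: int = 5
    overlap_cluster_size: int = 4
    n_forest_missing: int = 0
    n_extinct_in_wild: int = 1
    add_decoy_features: bool = True
    lat_limit_deg: float = 50.0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        for name in ("forest_fractions", "restoration_fractions", "protection_fractions"):
            vals = getattr(self, name)
            if vals is not None:
                if len(vals) != self.n_species:
                    raise ValueError(f"{name} must have length n_species")
                if any(not (0.0 <= v <= 1.0) for v in vals):
                    raise ValueError(f"{name} values must lie in [0, 1]")
        if not (0 <= self.overlap_cluster_size <= self.n_species):
            raise ValueError("overlap_cluster_size out of range")
        if self.n_forest_missing > self.n_species - self.overlap_cluster_size:
            raise ValueError("n_forest_missing exceeds available (non-cluster) species")


@dataclass
class GroundTruth:
    """What the generator engineered, for recovery checks."""

    species: pd.DataFrame  # per-species targets and realised fractions
    cluster_species: list[str]
    cluster_zone: BaseGeometry | None  # lon/lat polygon of the shared overlap


@dataclass
class SyntheticScenario:
    seed: int
    params: ScenarioParams
    catalog: list[SpeciesRecord]
    ranges: dict[str, list[RangeFeature]] = field(default_factory=dict)
    forest_raster: Raster | None = None
    restoration_raster: Raster | None = None
    protected_areas: list[tuple[BaseGeometry, str]] = field(default_factory=list)
    countries: list[tuple[str, BaseGeometry]] = field(default_factory=list)
    landmass: BaseGeometry | None = None  # lon/lat
    ground_truth: GroundTruth | None = None
    metrics_frame: pd.DataFrame | None = None  # attribute-only fixtures

    def write(self, out_dir: str | Path) -> None:
        """Write the scenario in the same formats the pipeline reads."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_catalog_csv(self.catalog, out / "catalog.csv")
        feats = []
        for sid in sorted(self.ranges):
            for f in self.ranges[sid]:
                feats.append((f.geometry, {
                    "species_id": f.species_id,
                    "presence": f.presence_code,
                    "origin": f.origin_code,
                    "seasonal": f.seasonal_code,
                }))
        write_geojson(out / "ranges.geojson", feats)
        if self.forest_raster is not None:
            self.forest_raster.to_geotiff(out / "forest.tif")
        if self.restoration_raster is not None:
            self.restoration_raster.to_geotiff(out / "restoration.tif")
        write_geojson(out / "protected_areas.geojson",
                      [(g, {"iucn_category": c}) for g, c in self.protected_areas])
        write_geojson(out / "countries.geojson",
                      [(g, {"name": n}) for n, g in self.countries])
        if self.landmass is not None:
            write_geojson(out / "landmass.geojson", [(self.landmass, {})])
        if self.ground_truth is not None:
            truth = {
                "species": json.loads(
                    self.ground_truth.species.to_json(orient="index")),
                "cluster_species": self.ground_truth.cluster_species,
            }
            (out / "ground_truth.json").write_text(json.dumps(truth, sort_keys=True))
        if self.metrics_frame is not None:
            self.metrics_frame.to_csv(out / "true_metrics.csv", index=False)


# ---------------------------------------------------------------------------
# Geometric scenario generation
# ---------------------------------------------------------------------------

_STATUS_CYCLE = ("CR", "EN", "VU", "NT")
_CLASS_CYCLE = ("Aves", "Mammalia", "Amphibia")


def _place_ranges(params: ScenarioParams, rng: np.random.Generator,
                  landmass_ea: BaseGeometry) -> list[tuple[Point, float]]:
    """Disk centres/radii (equal-area metres): a shared cluster, rest disjoint."""
    minx, miny, maxx, maxy = landmass_ea.bounds
    # reserve a strip at the top of the landmass for decoy features
    decoy_strip = 12_000.0 if params.add_decoy_features else 0.0
    maxy_use = maxy - decoy_strip
    lo, hi = params.range_area_km2
    radii = np.sqrt(rng.uniform(lo, hi, size=params.n_species) / math.pi) * 1000.0

    placed: list[tuple[Point, float]] = []
    k = params.overlap_cluster_size
    if k:
        cx = 0.5 * (minx + maxx)
        cy = 0.5 * (miny + maxy_use)
        for i in range(k):
            ang = 2.0 * math.pi * i / max(k, 1)
            # offset well under the radius, so all cluster disks share a zone
            off = 0.35 * radii[i]
            placed.append((Point(cx + off * math.cos(ang), cy + off * math.sin(ang)), radii[i]))
    cluster_envelope = (
        shapely.union_all([p.buffer(r, quad_segs=8) for p, r in placed]) if placed else None)

    for i in range(k, params.n_species):
        r = radii[i]
        ok = False
        for _ in range(2000):
            x = rng.uniform(minx + r + 2000.0, maxx - r - 2000.0)
            y = rng.uniform(miny + r + 2000.0, maxy_use - r - 2000.0)
            pt = Point(x, y)
            if cluster_envelope is not None and pt.buffer(r + 2000.0, quad_segs=8).intersects(cluster_envelope):
                continue
            if any(pt.distance(q) < r + rq + 2000.0 for q, rq in placed[k:]):
                continue
            ok = True
            break
        if not ok:
            raise InfeasibleScenarioError(
                f"cannot place {params.n_species} disjoint ranges of "
                f"{lo}-{hi} km² on this landmass")
        placed.append((pt, r))
    return placed


def _fill_raster_greedy(rng: np.random.Generator, shape: tuple[int, int],
                        per_species_pixels: list[np.ndarray],
                        targets: Sequence[float],
                        forbidden: np.ndarray | None = None,
                        exact: Sequence[bool] | None = None) -> np.ndarray:
    """Select pixels so each species' selected fraction hits its target.

    Species are processed in order; pixels already selected inside a range
    (from an earlier, overlapping range) count toward its target, and
    top-ups prefer pixels no earlier range touched, so shared zones are not
    progressively densified. For species with engineered-disjoint ranges
    (``exact``) the realised count is guaranteed within one pixel of the
    target; for deliberately overlapping ranges the realised fraction may
    drift above the target and is recorded in the ground truth. A target
    that cannot be *reached* (too few free pixels) raises
    :class:`InfeasibleScenarioError`.
    """
    selected = np.zeros(shape, dtype=bool)
    processed = np.zeros(shape, dtype=bool)
    for i, flat_idx in enumerate(per_species_pixels):
        n_pix = flat_idx.size
        if n_pix == 0:
            continue
        target = int(round(targets[i] * n_pix))
        flat_sel = selected.ravel()[flat_idx]
        current = int(flat_sel.sum())
        must_be_exact = exact is None or exact[i]
        if current > target + 1 and must_be_exact:
            raise InfeasibleScenarioError(
                f"species #{i}: overlap forces {current} selected pixels, target {target}")
        if current < target:
            pool = flat_idx[~flat_sel]
            if forbidden is not None:
                pool = pool[~forbidden.ravel()[pool]]
            need = target - current
            if pool.size < need:
                raise InfeasibleScenarioError(
                    f"species #{i}: only {pool.size} free pixels for target {target}")
            fresh = pool[~processed.ravel()[pool]]
            if fresh.size >= need:
                pick = rng.choice(fresh, size=need, replace=False)
            else:
                stale = pool[processed.ravel()[pool]]
                pick = np.concatenate([
                    fresh, rng.choice(stale, size=need - fresh.size, replace=False)])
            selected.ravel()[pick] = True
        processed.ravel()[flat_idx] = True
    return selected


def _protected_polygon(disk_ea: BaseGeometry, fraction: float) -> BaseGeometry:
    """West-side slice of a range with area = fraction × range area (±0.1%)."""
    minx, miny, maxx, maxy = disk_ea.bounds
    total = disk_ea.area
    lo, hi = minx, maxx
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        part = disk_ea.intersection(box(minx - 1.0, miny - 1.0, mid, maxy + 1.0))
        if part.area < fraction * total:
            lo = mid
        else:
            hi = mid
    return disk_ea.intersection(box(minx - 1.0, miny - 1.0, 0.5 * (lo + hi), maxy + 1.0))


def _make_catalog(params: ScenarioParams, rng: np.random.Generator) -> list[SpeciesRecord]:
    records = []
    for i in range(params.n_species):
        sid = f"sp{i:03d}"
        status = "EW" if i < params.n_extinct_in_wild else _STATUS_CYCLE[i % 4]
        benign = bool(rng.random() < params.benign_fraction)
        p_inv = params.p_invasive_benign if benign else params.p_invasive_reintro
        p_res = params.p_restoration_benign if benign else params.p_restoration_reintro
        actions = set()
        if rng.random() < p_inv:
            actions.add("invasive_species_control")
        if rng.random() < p_res:
            actions.add("habitat_restoration")
        records.append(SpeciesRecord(
            species_id=sid,
            scientific_name=f"Synthetica specius{i}",
            taxon_class=_CLASS_CYCLE[i % 3],
            redlist_category=status,
            is_terrestrial=True,
            is_forest_dependent=True,
            ct_recommended=True,
            ct_category="benign_introduction" if benign else "reintroduction",
            actions_recommended=frozenset(actions),
            island_dweller=bool(rng.random() < 0.5),
            has_recovery_plan=bool(rng.random() < 0.5),
            has_active_ct_program=bool(rng.random() < 0.55),
        ))
    return records


def generate_scenario(params: ScenarioParams | None = None, seed: int = 0) -> SyntheticScenario:
    """Build a complete synthetic scenario (deterministic for fixed seed)."""
    params = params or ScenarioParams()
    params.validate()
    rng = np.random.default_rng(seed)

    landmass = box(params.lon_min, params.lat_min, params.lon_max, params.lat_max)
    landmass_ea = to_equal_area(landmass)

    placed = _place_ranges(params, rng, landmass_ea)
    disks_ea = [pt.buffer(r, quad_segs=64) for pt, r in placed]

    # raster grid over the landmass (equal-area plane, square pixels)
    px = params.pixel_km * 1000.0
    minx, miny, maxx, maxy = landmass_ea.bounds
    x0 = math.floor(minx / px) * px
    y0 = math.ceil(maxy / px) * px
    ncol = int(math.ceil((maxx - x0) / px))
    nrow = int(math.ceil((y0 - miny) / px))
    jj, ii = np.meshgrid(np.arange(ncol), np.arange(nrow))
    cx = x0 + (jj + 0.5) * px
    cy = y0 - (ii + 0.5) * px

    per_species_pixels = []
    for disk in disks_ea:
        shapely.prepare(disk)
        mask = shapely.contains_xy(disk, cx.ravel(), cy.ravel())
        per_species_pixels.append(np.nonzero(mask)[0])

    n = params.n_species
    f_t = (np.asarray(params.forest_fractions, dtype=float)
           if params.forest_fractions is not None else rng.uniform(0.05, 0.85, n))
    if params.restoration_fractions is not None:
        r_t = np.asarray(params.restoration_fractions, dtype=float)
    else:
        r_t = rng.uniform(0.1, 1.0, n) * np.minimum(0.5, 1.0 - f_t)
    if (f_t + r_t > 1.0 + 1e-9).any():
        raise InfeasibleScenarioError("forest + restoration fraction exceeds 1 for some species")
    k = params.overlap_cluster_size
    if k >= 2:
        # cluster ranges overlap heavily; a shared per-cluster target keeps
        # the greedy pixel fill feasible and the realised fractions close
        f_t[:k] = f_t[0]
        r_t[:k] = r_t[0]
    p_t = (np.asarray(params.protection_fractions, dtype=float)
           if params.protection_fractions is not None else rng.uniform(0.0, 0.5, n))

    exact = [i >= k for i in range(n)] if k >= 2 else None
    forest_sel = _fill_raster_greedy(rng, (nrow, ncol), per_species_pixels, f_t,
                                     exact=exact)
    rest_sel = _fill_raster_greedy(rng, (nrow, ncol), per_species_pixels, r_t,
                                   forbidden=forest_sel, exact=exact)

    forest_data = np.where(forest_sel, 1.0, 0.0).astype(np.float32)
    nodata = -1.0
    missing_ids: list[str] = []
    if params.n_forest_missing:
        # knock out the forest layer over the LAST ranges (never the cluster)
        for i in range(n - params.n_forest_missing, n):
            forest_data.ravel()[per_species_pixels[i]] = nodata
            missing_ids.append(f"sp{i:03d}")
    forest_raster = Raster(forest_data, x0=x0, y0=y0, px=px, py=px,
                           crs="equal_area", nodata=nodata)
    restoration_raster = Raster(np.where(rest_sel, 1.0, 0.0).astype(np.float32),
                                x0=x0, y0=y0, px=px, py=px, crs="equal_area")

    # protected areas: a west-side slice of each range; one decoy polygon
    # with a non-I–VI category that the analysis must ignore
    protected_areas: list[tuple[BaseGeometry, str]] = []
    pa_parts_ea = []
    for i, disk in enumerate(disks_ea):
        if p_t[i] <= 0.0:
            continue
        part = _protected_polygon(disk, p_t[i])
        pa_parts_ea.append(part)
        protected_areas.append((from_equal_area(part), "II"))
    # realised protection is measured against the dissolved union of ALL
    # reserves: overlapping ranges see each other's protected slices
    pa_union_ea = shapely.union_all(pa_parts_ea) if pa_parts_ea else shapely.Polygon()
    realized_p = np.array([disk.intersection(pa_union_ea).area / disk.area
                           for disk in disks_ea])
    decoy_pa = box(minx, maxy - 8000.0, minx + 20000.0, maxy - 1000.0)
    protected_areas.append((from_equal_area(decoy_pa), "Not Reported"))

    # countries: Voronoi partition of the landmass
    pts = MultiPoint([Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
                      for _ in range(params.n_countries)])
    regions = voronoi_diagram(pts, envelope=landmass_ea.buffer(1e5))
    countries: list[tuple[str, BaseGeometry]] = []
    for idx, pt in enumerate(pts.geoms):
        region = next(g for g in regions.geoms if g.contains(pt))
        countries.append((f"Country_{chr(65 + idx)}", from_equal_area(region.intersection(landmass_ea))))

    catalog = _make_catalog(params, rng)

    # range features: the real range plus (optionally) decoy features the
    # presence/origin/seasonal filter must drop
    ranges: dict[str, list[RangeFeature]] = {}
    decoy_y = maxy - 6000.0
    for i, disk in enumerate(disks_ea):
        sid = f"sp{i:03d}"
        rec = catalog[i]
        presence = 5 if rec.redlist_category == "EW" else int(rng.choice([1, 2]))
        feats = [RangeFeature(species_id=sid, geometry=from_equal_area(disk),
                              presence_code=presence, origin_code=1, seasonal_code=0)]
        if params.add_decoy_features:
            patch = Point(minx + 30000.0 + 12000.0 * i, decoy_y).buffer(4000.0, quad_segs=16)
            feats.append(RangeFeature(species_id=sid, geometry=from_equal_area(patch),
                                      presence_code=6, origin_code=1, seasonal_code=0))
            patch2 = Point(minx + 36000.0 + 12000.0 * i, decoy_y).buffer(3000.0, quad_segs=16)
            feats.append(RangeFeature(species_id=sid, geometry=from_equal_area(patch2),
                                      presence_code=1, origin_code=1, seasonal_code=4))
        ranges[sid] = feats

    # realised fractions from the final rasters (pixel-count ratios)
    rows = []
    fmask = forest_raster.valid_mask().ravel()
    fdat = forest_raster.data.ravel()
    rdat = restoration_raster.data.ravel()
    for i in range(n):
        idx = per_species_pixels[i]
        valid = fmask[idx]
        n_valid = int(valid.sum())
        rows.append({
            "species_id": f"sp{i:03d}",
            "n_pixels": int(idx.size),
            "target_forest": float(f_t[i]),
            "target_restoration": float(r_t[i]),
            "target_protected": float(p_t[i]),
            "realized_forest": (float(fdat[idx][valid].sum()) / n_valid) if n_valid else np.nan,
            "realized_restoration": float(rdat[idx].sum()) / idx.size if idx.size else np.nan,
            "realized_protected": float(realized_p[i]),
            "forest_missing": f"sp{i:03d}" in missing_ids,
            "in_cluster": i < params.overlap_cluster_size,
        })
    truth_df = pd.DataFrame(rows)

    cluster_ids = [f"sp{i:03d}" for i in range(params.overlap_cluster_size)]
    cluster_zone = None
    if params.overlap_cluster_size >= 2:
        zone = disks_ea[0]
        for d in disks_ea[1:params.overlap_cluster_size]:
            zone = zone.intersection(d)
        cluster_zone = from_equal_area(zone)

    return SyntheticScenario(
        seed=seed, params=params, catalog=catalog, ranges=ranges,
        forest_raster=forest_raster, restoration_raster=restoration_raster,
        protected_areas=protected_areas, countries=countries,
        landmass=landmass,
        ground_truth=GroundTruth(species=truth_df, cluster_species=cluster_ids,
                                 cluster_zone=cluster_zone),
    )


# ---------------------------------------------------------------------------
# Published-margins fixture (attribute-only)
# ---------------------------------------------------------------------------

#: Class × Red List status counts of the published 152-species assessment.
TABLE1_MARGINS = {
    "Amphibia": {"CR": 5, "EN": 3, "EW": 0, "NT": 2, "VU": 2},
    "Aves": {"CR": 29, "EN": 27, "EW": 5, "NT": 4, "VU": 25},
    "Mammalia": {"CR": 8, "EN": 17, "EW": 0, "NT": 8, "VU": 17},
}

#: Published per-country hotspot areas (km²) at 4/5/6 overlapping species.
TABLE2_AREAS = {
    "Australia": (6121, 591, 64),
    "Bhutan": (3541, 8172, 93),
    "China": (14306, 84, 0),
    "India": (5444, 9987, 67),
    "Myanmar": (5131, 0, 0),
    "Nepal": (29967, 16912, 0),
    "Thailand": (868, 0, 0),
}

_N_REINTRO, _N_BENIGN = 115, 37


def _ladder(n: int, total: float, start: float) -> np.ndarray:
    """n ascending positive values beginning at ``start`` summing to ``total``."""
    if n == 1:
        return np.array([total])
    d = (total - n * start) / (n * (n - 1) / 2.0)
    return start + d * np.arange(n)


def _fixture_group(n: int, invasive: set[int], missing: set[int], zero_prot: set[int],
                   good: set[int], protected_sorted: np.ndarray,
                   forest_values: np.ndarray, rest_zero: set[int],
                   rest_high: set[int]) -> pd.DataFrame:
    """Assemble one CT group's per-species attribute/metric rows."""
    pos = sorted(set(range(n)) - zero_prot)
    prot = np.zeros(n)
    prot[pos] = protected_sorted
    present = sorted(set(range(n)) - missing)
    forest = np.full(n, np.nan)
    forest[present] = forest_values
    rest = np.empty(n)
    hi_vals = iter(55.0 + 5.0 * np.arange(len(rest_high)))
    mid = 10.0
    for i in range(n):
        if i in rest_zero:
            rest[i] = 0.0
        elif i in rest_high:
            rest[i] = next(hi_vals)
        else:
            rest[i] = mid
            mid = 10.0 + (mid + 7.0) % 40.0
    return pd.DataFrame({
        "idx": np.arange(n),
        "invasive": [i in invasive for i in range(n)],
        "forest_missing": [i in missing for i in range(n)],
        "pct_protected": prot,
        "pct_forest_cover": forest,
        "pct_restoration": rest,
        "good": [i in good for i in range(n)],
    })


def paper_margin_fixture() -> SyntheticScenario:
    """Catalog + per-species metrics reproducing the published margins.

    The construction is deterministic index-range assignment; every printed
    marginal constraint is re-checked by assertion at build time:

    * class × status counts and the 152 grand total;
    * 115 reintroduction / 37 benign-introduction split;
    * 71 species recommended invasive-species control (24 benign), 63
      recommended habitat restoration (10 benign) — the pinned
      margin-consistent contingency cells;
    * 67 species satisfying the good-candidate composite;
    * protected-percentage medians 7.4 (reintroduction) and 0.9 (benign),
      33 species (22%) with no protected area, group means 13.3/12.0;
    * 38 species (25%) with forest cover unobservable, 21 of them benign;
      mean forest cover 44% (reintroduction) and 61% (benign) among
      observed;
    * 55 species (36%) with no restoration potential (33 reintroduction,
      22 benign), 11 species above 50%;
    * 78 island dwellers, 76 recovery plans, 84 active CT programs, 46 with
      both.
    """
    # ---- reintroduction group (n=115) ----
    inv_r = set(range(0, 47))
    good_r = set(range(47, 109))            # 62 species
    miss_r = set(range(0, 14)) | set(range(109, 112))      # 17
    zero_r = set(range(14, 29)) | set(range(112, 115))     # 18
    n_pos_r = 115 - 18                       # 97 positive protected values
    low = np.linspace(0.5, 7.2, 39)
    high = _ladder(57, 1532.0 - low.sum() - 7.4, 7.6)
    prot_r = np.concatenate([low, [7.4], high])
    assert prot_r.size == n_pos_r and (np.diff(prot_r) > 0).all() and prot_r.max() < 100
    forest_r = _ladder(98, 44.0 * 98, 10.0)
    rest_zero_r = set(range(14, 29)) | set(range(109, 115)) | set(range(0, 12))  # 33
    rest_high_r = set(range(47, 57))        # 10 species above 50%
    grp_r = _fixture_group(115, inv_r, miss_r, zero_r, good_r, prot_r,
                           forest_r, rest_zero_r, rest_high_r)

    # ---- benign-introduction group (n=37) ----
    inv_b = set(range(0, 24))
    good_b = set(range(24, 29))             # 5 species
    miss_b = set(range(0, 17)) | set(range(29, 33))        # 21
    zero_b = set(range(17, 24)) | set(range(33, 37)) | {13, 14, 15, 16}  # 15
    prot_b = np.concatenate([[0.2, 0.4, 0.6, 0.9], _ladder(18, 444.0 - 2.1, 2.0)])
    assert prot_b.size == 37 - 15 and (np.diff(prot_b) > 0).all() and prot_b.max() < 100
    forest_b = _ladder(16, 61.0 * 16, 30.0)
    rest_zero_b = set(range(0, 18)) | set(range(33, 37))    # 22
    rest_high_b = {24}
    grp_b = _fixture_group(37, inv_b, miss_b, zero_b, good_b, prot_b,
                           forest_b, rest_zero_b, rest_high_b)

    # ---- interleave into the global catalog ----
    class_status: list[tuple[str, str]] = []
    for cls in ("Amphibia", "Aves", "Mammalia"):
        for st, cnt in TABLE1_MARGINS[cls].items():
            class_status.extend([(cls, st)] * cnt)
    assert len(class_status) == 152

    island_r = set(range(17, 62))           # 45 reintroduction islanders
    island_b = set(range(0, 33))            # 33 benign islanders

    records: list[SpeciesRecord] = []
    metric_rows: list[dict] = []
    program = set(range(0, 84))
    recovery = set(range(38, 114))          # |recovery|=76, overlap with program = 46
    habrest_r = set(range(47, 100))         # 53 reintroduction, habitat restoration
    habrest_b = set(range(24, 34))          # 10 benign

    for g in range(152):
        if g < 115:
            ct, i, grp = "reintroduction", g, grp_r
            island, habrest = i in island_r, i in habrest_r
        else:
            ct, i, grp = "benign_introduction", g - 115, grp_b
            island, habrest = i in island_b, i in habrest_b
        row = grp.iloc[i]
        cls, st = class_status[g]
        actions = set()
        if row["invasive"]:
            actions.add("invasive_species_control")
        if habrest:
            actions.add("habitat_restoration")
        sid = f"fx{g:03d}"
        records.append(SpeciesRecord(
            species_id=sid, scientific_name=f"Fixta species{g}",
            taxon_class=cls, redlist_category=st,
            is_terrestrial=True, is_forest_dependent=True, ct_recommended=True,
            ct_category=ct, actions_recommended=frozenset(actions),
            island_dweller=island,
            has_recovery_plan=g in recovery,
            has_active_ct_program=g in program,
        ))
        missing = bool(row["forest_missing"])
        metric_rows.append({
            "species_id": sid,
            "pct_forest_cover": row["pct_forest_cover"],
            "pct_restoration": float(row["pct_restoration"]),
            "pct_protected": float(row["pct_protected"]),
            "forest_data_coverage": 0.1 if missing else 1.0,
            "good_candidate": bool(row["good"]),
        })
    metrics = pd.DataFrame(metric_rows)

    _assert_fixture(records, metrics)
    return SyntheticScenario(seed=0, params=ScenarioParams(n_species=152),
                             catalog=records, metrics_frame=metrics)


def _assert_fixture(records: list[SpeciesRecord], metrics: pd.DataFrame) -> None:
    from .habitat_metrics import HabitatMetrics, good_candidate

    by_ct: dict[str, list[int]] = {"reintroduction": [], "benign_introduction": []}
    for k, rec in enumerate(records):
        by_ct[rec.ct_category].append(k)
    assert len(by_ct["reintroduction"]) == _N_REINTRO
    assert len(by_ct["benign_introduction"]) == _N_BENIGN

    inv = [("invasive_species_control" in r.actions_recommended) for r in records]
    hab = [("habitat_restoration" in r.actions_recommended) for r in records]
    assert sum(inv) == 71 and sum(inv[115:]) == 24
    assert sum(hab) == 63 and sum(hab[115:]) == 10

    n_good = 0
    for k, rec in enumerate(records):
        row = metrics.iloc[k]
        m = HabitatMetrics(
            species_id=rec.species_id,
            pct_forest_cover=None if pd.isna(row["pct_forest_cover"]) else float(row["pct_forest_cover"]),
            pct_restoration=float(row["pct_restoration"]),
            pct_protected=float(row["pct_protected"]),
            forest_data_coverage=float(row["forest_data_coverage"]),
        )
        flag = good_candidate(m, rec)
        assert flag == bool(row["good_candidate"]), rec.species_id
        n_good += flag
    assert n_good == 67

    prot_r = metrics["pct_protected"].to_numpy()[:115]
    prot_b = metrics["pct_protected"].to_numpy()[115:]
    assert abs(np.median(prot_r) - 7.4) < 1e-9
    assert abs(np.median(prot_b) - 0.9) < 1e-9
    assert int((metrics["pct_protected"] == 0).sum()) == 33
    assert int(metrics["pct_forest_cover"].isna().sum()) == 38
    assert int(metrics["pct_forest_cover"][115:].isna().sum()) == 21
    assert abs(np.nanmean(metrics["pct_forest_cover"][:115]) - 44.0) < 1e-9
    assert abs(np.nanmean(metrics["pct_forest_cover"][115:]) - 61.0) < 1e-9
    assert int((metrics["pct_restoration"] == 0).sum()) == 55
    assert int((metrics["pct_restoration"] > 50).sum()) == 11
    assert sum(r.island_dweller for r in records) == 78
    assert sum(r.has_recovery_plan for r in records) == 76
    assert sum(r.has_active_ct_program for r in records) == 84
    assert sum(r.has_recovery_plan and r.has_active_ct_program for r in records) == 46
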
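# Methods

## The assessment

`forestct` implements a global habitat-quality screen for forest-dependent
terrestrial vertebrates (amphibians, birds, mammals) that have conservation
translocation (CT) listed among their recommended conservation actions.
The pipeline answers, per species and per place: how much of the range is
still forested, how much could be reforested, how much is protected, and
where do several candidate species' ranges coincide with restoration
potential so that one restoration project could serve many translocations.

Stages, in execution order:

1. **Catalog filtering.** A species enters the candidate pool iff it is an
   amphibian, bird or mammal; terrestrial; forest dependent; has CT
   recommended; and is listed EW, CR, EN, VU or NT (Data Deficient and
   Least Concern are excluded). Forest dependence and the
   reintroduction/benign-introduction split are input attributes, not
   inferred: these judgements require life-history expertise (a lion is not
   forest dependent however its habitat codes read) and the source data do
   not encode a reproducible rule. An optional exclusion list drops species
   whose source data cannot distinguish subspecies.
2. **Range processing.** Range polygons carry the IUCN mapping-standard
   attributes. Retained portions: presence extant (1) or probably extant
   (2) — or, for Extinct-in-the-Wild species, extinct (5), since the
   historical range is exactly what a reintroduction would target — with
   origin native (1) or reintroduced (2); passage (seasonal 4) and
   presence-uncertain (6) portions are dropped. The mapping-standard code
   table is config-overridable. Retained features are repaired
   (make-valid), dissolved to one footprint per species, and clipped to
   |lat| ≤ 50°, the band that contains the candidate ranges.
3. **Habitat metrics.** Forest and restoration percentages use 1-km rasters
   with pixel-centre zonal semantics (half-open pixels, origin at the
   upper-left): a pixel belongs to a range iff its centre falls inside the
   footprint. The percentage is the positive-pixel area over the
   valid-pixel area; pixels flagged nodata leave the denominator. When
   valid pixels cover less than 50% of a range (configurable) the forest
   percentage is reported missing rather than extrapolated — satellite
   forest products skip many small oceanic islands, and a percentage from
   a sliver of range would be misleading. Protected coverage intersects
   the footprint with the dissolved union of protected areas restricted to
   IUCN categories I–VI, so stacked designations count once. The composite
   *good candidate* flag requires protected coverage > 0, observed forest
   cover > 0 and no invasive-species-control recommendation (thresholds
   configurable; the defaults are the weakest reading of "part of the
   range", which is the criterion the assessment states).
4. **Hexagon richness.** Footprints are counted on a tessellation of
   equal-area hexagons (target 10 km²/cell) built in the analysis
   projection plane, where every cell has *exactly* the target area. A
   species counts in a cell only when the intersection has positive area;
   boundary touches are ignored so shared edges never double-count.
   The literal reading of a "10 km² resolution" grid is cell *area*;
   10-km *spacing* (≈87 km² cells) is reachable through the same
   parameter if a user prefers that reading.
5. **Hotspots.** A hotspot cell has ≥ k species (default k=4) and at least
   one restorable pixel centre inside it. Hotspot area is tabulated per
   country at each exact species-count level; straddling cells are split
   by exact cell–country intersection area (not winner-takes-all), which
   conserves total area to floating-point precision. Counts above the top
   requested level can be collapsed into it.
6. **Group statistics.** Protected-range percentages are compared between
   CT categories with a two-sided Mann–Whitney U test (the distributions
   are zero-inflated and long-tailed, so a rank test rather than a t-test):
   exact enumeration when the pooled sample is ≤ 20 and tie-free, otherwise
   the normal approximation with tie-corrected variance and continuity
   correction. Association between CT category and each recommended action
   is tested with a 2×2 chi-square; the continuity (Yates) correction is on
   by default, matching the convention of the standard statistics
   environment for 2×2 tables, and the 80%-of-expected-counts-above-5
   assumption check is computed alongside. Significance is read at 0.05
   with no multiple-testing adjustment (two planned tests).

## Geospatial machinery

All vector data cross module boundaries as WGS84 lon/lat (GeoJSON is the
interchange format and is WGS84 by definition). Areas, grids and zonal
statistics are computed in a global equal-area projection — Mollweide on
the authalic sphere (R = 6 371 007.18 m), implemented in closed form with
Newton iteration for the parametric latitude. Geometries are densified to
0.05° segments before projecting so long edges stay area-faithful. The
projection is validated against an independent Monte-Carlo spherical-area
oracle (uniform-on-sphere sampling) to within 1%. Rasters are single-band
GeoTIFFs carrying pixel-scale/tiepoint tags, either in the analysis
projection (square 1-km pixels) or in lon/lat (pixel areas weighted by
cos latitude).

Numerical conventions worth knowing:

- Intersection predicates use a 10⁻⁹ relative-area epsilon so tessellation
  edges and floating-point slivers never flip a count.
- Country polygons are validated to be non-overlapping (relative sliver
  tolerance 10⁻⁹) before apportionment.
- Empty footprints are legal after filtering (area 0); asking for zonal
  statistics on one is an error, and the pipeline drops them beforehand.
- Unrecognised enum values in catalogs coerce to `other`/`unknown` with a
  logged warning rather than failing the load.

## The synthetic-data generator

Real inputs (Red List/BirdLife range downloads, Hansen-derived forest
extent, FLRO-derived restoration potential, WDPA polygons) cannot be
redistributed, so the generator emulates all five inputs with known ground
truth:

- **Ranges** are buffered points (disks) on a rectangular equatorial
  landmass — sufficient for every geometric contract, not for range-shape
  realism. Non-cluster ranges are placed disjoint by rejection sampling; a
  configurable cluster of k species (default 4) shares an engineered
  overlap zone for hotspot recovery. Each species also gets decoy features
  with presence-uncertain and passage codes that correct filtering must
  drop.
- **Rasters** (1-km pixels in the analysis projection) are filled by
  sampling pixels inside each range to hit per-species target fractions
  f_s (forest) and r_s (restoration, drawn from non-forest pixels): exact
  to one pixel for disjoint ranges, recorded as realised fractions for
  cluster members (top-ups prefer pixels no earlier range touched so
  shared zones are not progressively densified). Unreachable targets
  raise an explicit infeasibility error. A configurable number of species
  have their forest pixels set to nodata to emulate the missing-island
  pattern.
- **Protected areas** are west-side slices of each range cut by bisection
  to the target protection fraction (±0.1%), all category II, plus one
  decoy polygon with a non-I–VI category that must be ignored. Ground
  truth records protection against the dissolved union of all reserves,
  since overlapping ranges legitimately see each other's reserves.
- **Countries** are a Voronoi partition of the landmass.
- **The catalog** draws CT category and action recommendations from
  configurable conditional probabilities whose defaults equal the pinned
  2×2 cells of the published assessment (24/37 and 47/115 for invasive
  control; 10/37 and 53/115 for habitat restoration).

Default scenario size is 20 species on a ~3°×3° landmass — small enough
that a full run takes seconds, large enough that every range holds ≥ 800
pixels at 1 km, where pixelation error on a recovered fraction is well
under one percentage point. Passing tests on these landscapes demonstrates
the correctness of the geometry, zonal statistics and bookkeeping; they say
nothing about range-map quality, satellite-layer accuracy or the ecological
realism of disk-shaped ranges, which real applications must supply.

## The published-margins fixture

`paper_margin_fixture()` is an attribute-only catalog + metrics table that
reproduces the published marginal counts of the 152-species assessment
simultaneously: the class × status table (cells exactly; note the published
margin row contains a small internal inconsistency — the cells sum to
NT=14, VU=44 and grand total 152, while the printed NT/VU margins read
15/45, which would total 154; the fixture follows the cells), the 115/37
CT split, 71/63 action-recommendation totals, the 67-species good-candidate
composite (44%), protected-percentage medians 7.4/0.9 with 22% of species
at zero, the 25%-missing forest pattern with 21 benign-introduction species
missing and group means 44%/61%, restoration-potential zeros (36%), and the
island/recovery-plan/CT-program counts. Values between the pinned order
statistics are arithmetic ladders (ascending, sum-constrained) — the
fixture pins the printed marginal statistics, *not* the unpublished full
distributions, so statistics that depend on the whole distribution (e.g.
the rank-sum p-value) are not expected to match the published ones.

The published 2×2 chi-square statistics could not be reproduced exactly:
exhaustive enumeration over all margin-consistent tables (rows 37/115,
first column 71 or 63) shows no integer table yields 5.9405 or 3.4833 to
four decimals under either correction convention, implying the published
tests used slightly different margins than the stated species counts. The
package pins the nearest direction-consistent Yates-corrected tables
([[24,13],[47,68]] → χ²=5.5471, p=0.019; [[10,27],[53,62]] → χ²=3.4418,
p=0.064) as regression fixtures; both preserve the published significance
conclusions at 0.05.

Likewise the published per-country hotspot table carries ±3 km² of internal
rounding drift (its Australia row and level-4 column do not sum exactly);
the `HotspotTable` reconstruction reconciles margins from the printed cells
exactly and therefore lands at 101,348 km² against the printed 101,346.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `cell_area_km2` | 10 | hexagon cell area (km²); exact in the projected backend |
| `lat_limit_deg` | 50 | latitude band half-width (degrees) |
| `hotspot_min_species` | 4 | minimum overlapping species for a hotspot cell |
| `hotspot_levels` | (4, 5, 6) | species-count columns of the country table |
| `forest_threshold` | 0 | canopy value above which a pixel is forest (supports binary extent and continuous percent-cover layers) |
| `min_forest_coverage` | 0.5 | valid-pixel fraction below which forest % is missing |
| good-candidate thresholds | >0 / >0 | minimum protected % and forest % |

## Known limitations

- Vector I/O is GeoJSON; rasters are GeoTIFF in lon/lat or the analysis
  projection. Other CRSs/formats must be converted upstream.
- One projected-plane hexagon backend; an icosahedral discrete-global-grid
  backend is recognised in the interface but not implemented (it would
  require external DGG tooling). None of the downstream statistics depend
  on grid geometry beyond equal-area cells.
- The Mann–Whitney exact path enumerates only tie-free pooled samples ≤ 20;
  beyond that the corrected normal approximation is used (validated within
  0.02 of enumeration at n = 10 + 10).
- Seasonal migration, marine ranges, habitat connectivity and climate
  suitability are out of scope.
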
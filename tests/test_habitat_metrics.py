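"""Zonal forest/restoration percentages, protected coverage, composite flag."""

import numpy as np
import pytest
import shapely
from shapely.geometry import Point, box

from forestct.geoutil import KM2_PER_M2, Raster, from_equal_area, to_equal_area
from forestct.habitat_metrics import (
    HabitatMetrics,
    compute_metrics,
    good_candidate,
    percent_protected,
    percent_raster_overlap,
)
from forestct.range_io import SpeciesFootprint
from forestct.species_catalog import SpeciesRecord


def _footprint_ea(geom_ea, sid="sp"):
    lonlat = from_equal_area(geom_ea)
    return SpeciesFootprint(species_id=sid, geometry=lonlat,
                            area_km2=geom_ea.area * KM2_PER_M2,
                            n_features_retained=1, n_features_dropped=0)


def _record(actions=()):
    return SpeciesRecord(species_id="sp", scientific_name="A b", taxon_class="Aves",
                         redlist_category="EN", is_terrestrial=True,
                         is_forest_dependent=True, ct_recommended=True,
                         ct_category="reintroduction",
                         actions_recommended=frozenset(actions))


class TestPercentRasterOverlap:
    def test_uniform_forest_gives_100_and_full_coverage(self):
        fp = _footprint_ea(box(5_000, 5_000, 45_000, 45_000))
        raster = Raster(np.ones((50, 50)), x0=0.0, y0=50_000.0, px=1000.0, py=1000.0)
        pct, cov = percent_raster_overlap(fp, raster)
        assert pct == pytest.approx(100.0)
        assert cov == pytest.approx(1.0, rel=0.02)

    def test_footprint_outside_raster_is_missing(self):
        fp = _footprint_ea(box(200_000, 0, 240_000, 40_000))
        raster = Raster(np.ones((50, 50)), x0=0.0, y0=50_000.0, px=1000.0, py=1000.0)
        pct, cov = percent_raster_overlap(fp, raster)
        assert pct is None and cov == 0.0

    def test_striped_raster_matches_pixel_center_oracle(self):
        data = np.zeros((40, 40))
        data[:, ::2] = 1.0  # vertical 1-km stripes
        raster = Raster(data, x0=0.0, y0=40_000.0, px=1000.0, py=1000.0)
        geom = box(3_200, 7_500, 31_700, 33_200)
        fp = _footprint_ea(geom)
        pct, cov = percent_raster_overlap(fp, raster)
        rows, cols = np.mgrid[0:40, 0:40]
        xs, ys = (cols + 0.5) * 1000.0, 40_000.0 - (rows + 0.5) * 1000.0
        inside = shapely.contains_xy(geom, xs.ravel(), ys.ravel())
        expected = 100.0 * data.ravel()[inside].sum() / inside.sum()
        assert pct == pytest.approx(expected, rel=1e-12)

    def test_nodata_excluded_from_denominator(self):
        data = np.ones((20, 20))
        data[:, 10:] = -1.0  # right half unobserved
        raster = Raster(data, x0=0.0, y0=20_000.0, px=1000.0, py=1000.0, nodata=-1.0)
        fp = _footprint_ea(box(1_000, 1_000, 19_000, 19_000))
        pct, cov = percent_raster_overlap(fp, raster)
        assert pct == pytest.approx(100.0)  # all *valid* pixels are forest
        assert cov == pytest.approx(0.5, abs=0.05)

    def test_empty_footprint_is_an_error(self):
        fp = SpeciesFootprint("sp", shapely.Polygon(), 0.0, 0, 0)
        raster = Raster(np.ones((5, 5)), x0=0.0, y0=5_000.0, px=1000.0, py=1000.0)
        with pytest.raises(ValueError, match="empty footprint"):
            percent_raster_overlap(fp, raster)

    def test_scale_invariance_of_percentage(self):
        # same forest pattern at 1× and 3× linear scale → same percentage
        data = np.kron(np.indices((10, 10)).sum(0) % 2, np.ones((2, 2)))
        pcts = []
        for scale in (1.0, 3.0):
            raster = Raster(data, x0=0.0, y0=20_000.0 * scale,
                            px=1000.0 * scale, py=1000.0 * scale)
            fp = _footprint_ea(box(2_000 * scale, 2_000 * scale,
                                   18_000 * scale, 18_000 * scale))
            pct, _ = percent_raster_overlap(fp, raster)
            pcts.append(pct)
        assert pcts[0] == pytest.approx(pcts[1], abs=2.0)


class TestPercentProtected:
    def test_footprint_equal_to_single_category_ii_polygon(self):
        geom_ea = Point(50_000, 0).buffer(20_000, quad_segs=64)
        fp = _footprint_ea(geom_ea)
        pa = [(from_equal_area(geom_ea), "II")]
        assert percent_protected(fp, pa) == pytest.approx(100.0, abs=0.01)

    def test_overlapping_polygons_dissolved_not_double_counted(self):
        geom_ea = box(0, 0, 40_000, 40_000)
        fp = _footprint_ea(geom_ea)
        half = from_equal_area(box(0, 0, 20_000, 40_000))
        pa = [(half, "I"), (half, "Ia")]  # same half, twice
        assert percent_protected(fp, pa) == pytest.approx(50.0, abs=0.5)

    def test_non_i_to_vi_categories_ignored(self):
        geom_ea = box(0, 0, 40_000, 40_000)
        fp = _footprint_ea(geom_ea)
        pa = [(from_equal_area(geom_ea), "Not Reported"),
              (from_equal_area(box(0, 0, 10_000, 40_000)), "IV")]
        assert percent_protected(fp, pa) == pytest.approx(25.0, abs=0.3)

    def test_random_polygons_match_monte_carlo_oracle(self, rng):
        geom_ea = box(0, 0, 60_000, 60_000)
        fp = _footprint_ea(geom_ea)
        pas_ea = [Point(rng.uniform(0, 60_000), rng.uniform(0, 60_000))
                  .buffer(rng.uniform(5_000, 25_000), quad_segs=32) for _ in range(6)]
        pa = [(from_equal_area(g), "II") for g in pas_ea]
        pct = percent_protected(fp, pa)
        union = shapely.union_all(pas_ea)
        pts_x = rng.uniform(0, 60_000, 1_000_000)
        pts_y = rng.uniform(0, 60_000, 1_000_000)
        shapely.prepare(union)
        mc = 100.0 * shapely.contains_xy(union, pts_x, pts_y).mean()
        assert pct == pytest.approx(mc, abs=1.0)

    def test_enlarging_union_is_monotone(self):
        geom_ea = box(0, 0, 40_000, 40_000)
        fp = _footprint_ea(geom_ea)
        small = [(from_equal_area(box(0, 0, 10_000, 40_000)), "II")]
        large = small + [(from_equal_area(box(10_000, 0, 25_000, 40_000)), "V")]
        assert percent_protected(fp, large) >= percent_protected(fp, small)


class TestGoodCandidate:
    @pytest.mark.parametrize("protected,forest,invasive,expected", [
        (7.4, 44.0, False, True),
        (0.0, 60.0, False, False),
        (7.4, 0.0, False, False),
        (7.4, None, False, False),
        (7.4, 44.0, True, False),
    ])
    def test_composite_rule(self, protected, forest, invasive, expected):
        m = HabitatMetrics(species_id="sp", pct_forest_cover=forest,
                           pct_restoration=10.0, pct_protected=protected,
                           forest_data_coverage=1.0)
        rec = _record({"invasive_species_control"} if invasive else ())
        assert good_candidate(m, rec) is expected


class TestComputeMetrics:
    def test_low_forest_coverage_reported_missing(self):
        fp = _footprint_ea(box(0, 0, 40_000, 40_000))
        forest = Raster(np.ones((40, 40)), x0=0.0, y0=40_000.0, px=1000.0, py=1000.0,
                        nodata=-1.0)
        forest.data[:, 10:] = -1.0  # only 25% of the range observed
        rest = Raster(np.zeros((40, 40)), x0=0.0, y0=40_000.0, px=1000.0, py=1000.0)
        m = compute_metrics(fp, _record(), forest, rest, [], min_forest_coverage=0.5)
        assert m.pct_forest_cover is None
        assert m.forest_data_coverage == pytest.approx(0.25, abs=0.03)
        assert not m.good_candidate

    def test_engineered_fraction_recovery_within_2pp(self, small_scenario):
        """Full-stack parameter recovery on the shared synthetic scenario."""
        from forestct.range_io import dissolve_and_clip, filter_range_features

        truth = small_scenario.ground_truth.species.set_index("species_id")
        by_id = {r.species_id: r for r in small_scenario.catalog}
        for sid, feats in small_scenario.ranges.items():
            rec = by_id[sid]
            kept = filter_range_features(feats, extinct_in_wild=rec.redlist_category == "EW")
            fp = dissolve_and_clip(kept, species_id=sid)
            m = compute_metrics(fp, rec, small_scenario.forest_raster,
                                small_scenario.restoration_raster,
                                small_scenario.protected_areas)
            row = truth.loc[sid]
            if row["forest_missing"]:
                assert m.pct_forest_cover is None
            else:
                assert m.pct_forest_cover == pytest.approx(
                    100.0 * row["realized_forest"], abs=2.0)
            assert m.pct_restoration == pytest.approx(
                100.0 * row["realized_restoration"], abs=2.0)
            assert m.pct_protected == pytest.approx(
                100.0 * row["realized_protected"], abs=2.0)
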
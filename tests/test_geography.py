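import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mobflux as mf
from mobflux.geography import EARTH_RADIUS_KM, read_geojson_centroids
from tests.conftest import make_district, random_geography


class TestHaversine:
    def test_identical_points_are_zero(self):
        assert mf.haversine_distance(10, 20, 10, 20) == 0.0

    def test_antipodal_arc_is_half_circumference(self):
        # closed form: pi * R for points on opposite sides of the equator
        assert mf.haversine_distance(0, 0, 0, 180) == pytest.approx(EARTH_RADIUS_KM * math.pi, rel=1e-12)

    def test_one_degree_equatorial_arc(self):
        assert mf.haversine_distance(0, 0, 0, 1) == pytest.approx(EARTH_RADIUS_KM * math.pi / 180, rel=1e-12)

    @given(
        lat1=st.floats(-90, 90), lon1=st.floats(-180, 180),
        lat2=st.floats(-90, 90), lon2=st.floats(-180, 180),
    )
    def test_symmetric_and_nonnegative(self, lat1, lon1, lat2, lon2):
        d = mf.haversine_distance(lat1, lon1, lat2, lon2)
        assert d >= 0
        assert d == pytest.approx(mf.haversine_distance(lat2, lon2, lat1, lon1), abs=1e-9)

    @pytest.mark.parametrize("bad", [(91, 0, 0, 0), (0, 200, 0, 0), (0, 0, -95, 0), (0, 0, 0, -181)])
    def test_out_of_range_coordinates_rejected(self, bad):
        with pytest.raises(mf.ValidationError):
            mf.haversine_distance(*bad)


class TestUrbanicity:
    @pytest.mark.parametrize(
        "frac,threshold,label",
        [(0.60, 0.5, "urban"), (0.05, 0.1, "rural"), (0.5, 0.5, "rural"), (0.11, 0.1, "urban")],
    )
    def test_threshold_classification(self, frac, threshold, label):
        assert mf.classify_urbanicity(frac, threshold) == label

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_urban_fraction(self, f1, f2, threshold):
        lo, hi = sorted([f1, f2])
        labels = {"rural": 0, "urban": 1}
        assert labels[mf.classify_urbanicity(lo, threshold)] <= labels[mf.classify_urbanicity(hi, threshold)]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(mf.ValidationError):
            mf.classify_urbanicity(1.2, 0.5)


class TestBuildGeography:
    def test_coincident_districts_have_zero_distance(self):
        geo = mf.build_geography([make_district(1), make_district(2)])
        assert np.all(geo.distance_matrix == 0)

    def test_matrix_symmetric_with_zero_diagonal(self, five_district_geo):
        d = five_district_geo.distance_matrix
        assert np.array_equal(d, d.T)
        assert np.all(np.diag(d) == 0)
        off = d[~np.eye(5, dtype=bool)]
        assert np.all(off > 0)

    def test_matrix_matches_pairwise_recomputation(self, five_district_geo):
        geo = five_district_geo
        for i, a in enumerate(geo.districts):
            for j, b in enumerate(geo.districts):
                expect = mf.haversine_distance(a.lat, a.lon, b.lat, b.lon)
                assert geo.distance_matrix[i, j] == pytest.approx(expect, abs=1e-9)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(11)
        geo = random_geography(rng, n=8)
        d = geo.distance_matrix
        n = geo.n
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-6

    def test_duplicate_ids_rejected(self):
        with pytest.raises(mf.ValidationError, match="duplicate"):
            mf.build_geography([make_district(1), make_district(1, lat=5.0)])

    def test_too_few_districts_rejected(self):
        with pytest.raises(mf.ValidationError):
            mf.build_geography([make_district(1)])

    def test_total_population_sums_districts(self, five_district_geo):
        assert five_district_geo.total_population == pytest.approx(
            sum(d.population for d in five_district_geo.districts)
        )

    def test_urban_labels_follow_threshold(self, five_district_geo):
        labels = five_district_geo.urbanicity
        assert labels == ["rural", "urban", "rural", "rural", "rural"]

    def test_csv_roundtrip(self, five_district_geo, tmp_path):
        path = tmp_path / "districts.csv"
        mf.write_district_csv(five_district_geo, path)
        back = mf.read_district_csv(path)
        assert back.ids == five_district_geo.ids
        assert np.allclose(back.distance_matrix, five_district_geo.distance_matrix)
        assert np.allclose(back.populations, five_district_geo.populations)


class TestGeoJSON:
    def test_polygon_centroid_used(self, tmp_path):
        # unit square centred at (lon=10.5, lat=20.5)
        def square(lon0, lat0, props):
            return {
                "type": "Feature",
                "properties": props,
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[
                        [lon0, lat0], [lon0 + 1, lat0], [lon0 + 1, lat0 + 1],
                        [lon0, lat0 + 1], [lon0, lat0],
                    ]],
                },
            }

        import json

        doc = {
            "type": "FeatureCollection",
            "features": [
                square(10, 20, {"id": "a", "region_id": "R1", "population": 100, "urban_fraction": 0.2}),
                square(12, 20, {"id": "b", "region_id": "R1", "population": 200, "urban_fraction": 0.6}),
            ],
        }
        p = tmp_path / "districts.geojson"
        p.write_text(json.dumps(doc))
        geo = read_geojson_centroids(p)
        assert geo.districts[0].lat == pytest.approx(20.5)
        assert geo.districts[0].lon == pytest.approx(10.5)
        assert geo.districts[1].lon == pytest.approx(12.5)


class TestAggregation:
    def _geo_and_trips(self):
        rows = [
            make_district(1, "R1", 100.0, 0.0, 0.0, 0.0),
            make_district(2, "R1", 300.0, 0.0, 1.0, 0.4),
            make_district(3, "R2", 200.0, 1.0, 0.0, 0.8),
            make_district(4, "R2", 400.0, 1.0, 1.0, 0.1),
        ]
        geo = mf.build_geography(rows)
        vals = np.arange(16, dtype=float).reshape(4, 4)
        trips = mf.TripMatrix(geo.ids, vals)
        return geo, trips

    def test_identity_mapping_preserves_everything(self):
        geo, trips = self._geo_and_trips()
        agg_geo, agg_trips = mf.aggregate_geography(geo, trips, {d.id: d.id for d in geo.districts})
        assert agg_geo.ids == geo.ids
        assert np.allclose(agg_geo.populations, geo.populations)
        m = trips.observed_mask
        assert np.allclose(agg_trips.values[m], trips.values[m])

    def test_single_unit_absorbs_all_trips(self):
        geo, trips = self._geo_and_trips()
        agg_geo, agg_trips = mf.aggregate_geography(geo, trips, {d.id: "U" for d in geo.districts})
        assert agg_geo.n == 1
        assert agg_trips.total == 0.0
        assert agg_geo.districts[0].population == pytest.approx(1000.0)

    def test_two_unit_sums_match_hand_enumeration(self):
        geo, trips = self._geo_and_trips()
        mapping = {"d1": "A", "d2": "A", "d3": "B", "d4": "B"}
        agg_geo, agg_trips = mf.aggregate_geography(geo, trips, mapping)
        v = trips.values
        # brute force: A->B pools pairs (1,3),(1,4),(2,3),(2,4)
        assert agg_trips.values[0, 1] == pytest.approx(v[0, 2] + v[0, 3] + v[1, 2] + v[1, 3])
        assert agg_trips.values[1, 0] == pytest.approx(v[2, 0] + v[2, 1] + v[3, 0] + v[3, 1])
        # population-weighted centroid of unit A: weights 100:300 at lon 0 and 1
        assert agg_geo.districts[0].lon == pytest.approx(0.75)
        assert agg_geo.districts[0].urban_fraction == pytest.approx((100 * 0.0 + 300 * 0.4) / 400)

    def test_population_and_cross_unit_trips_conserved(self):
        geo, trips = self._geo_and_trips()
        mapping = {"d1": "A", "d2": "B", "d3": "A", "d4": "B"}
        agg_geo, agg_trips = mf.aggregate_geography(geo, trips, mapping)
        assert agg_geo.total_population == pytest.approx(geo.total_population)
        v = trips.values
        within = v[0, 2] + v[2, 0] + v[1, 3] + v[3, 1]
        assert agg_trips.total == pytest.approx(trips.total - within)

    def test_missing_district_in_mapping_rejected(self):
        geo, trips = self._geo_and_trips()
        with pytest.raises(mf.ValidationError, match="d4"):
            mf.aggregate_geography(geo, trips, {"d1": "A", "d2": "A", "d3": "B"})
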
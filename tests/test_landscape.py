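"""Landscape generators: road density, tree edge effect, occupancy front,
nest thinning calibration, determinism."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point, box

from streetsurvey import (
    Extent,
    RoadNetwork,
    RoadSegment,
    generate_host_trees,
    generate_roads,
    make_front_occupancy,
    place_nests,
)
from streetsurvey.types import HostTree


class TestGenerateRoads:
    def test_zero_density_gives_no_roads(self, unit_extent):
        net = generate_roads(unit_extent, density=0.0, n_towns=3, seed=1)
        assert net.segments == []

    def test_fixed_seed_is_reproducible(self, unit_extent):
        a = generate_roads(unit_extent, density=1.0, n_towns=2, seed=42)
        b = generate_roads(unit_extent, density=1.0, n_towns=2, seed=42)
        assert [s.vertices for s in a] == [s.vertices for s in b]
        assert a.towns == b.towns

    def test_all_geometry_inside_extent(self, unit_extent):
        net = generate_roads(unit_extent, density=2.0, n_towns=3, seed=5)
        for s in net:
            for x, y in s.vertices:
                assert unit_extent.x_min <= x <= unit_extent.x_max
                assert unit_extent.y_min <= y <= unit_extent.y_max

    def test_mean_total_length_matches_density(self, unit_extent):
        # Monte-Carlo over seeds: E[total length] = density * area
        target = 2.0 * unit_extent.area
        lengths = np.array(
            [
                generate_roads(unit_extent, density=2.0, n_towns=2, seed=s).total_length
                for s in range(200)
            ]
        )
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert abs(lengths.mean() - target) <= 3 * se

    def test_streets_denser_near_towns(self):
        extent = Extent(0, 0, 20, 20)
        net = generate_roads(extent, density=2.0, n_towns=1, seed=11)
        tx, ty = net.towns[0]
        near = sum(
            1
            for s in net
            if np.hypot(s.vertices[0][0] - tx, s.vertices[0][1] - ty) < 4.0
        )
        # a 4 km disc is ~12.6/400 of the area; town bias concentrates far
        # more than that share of segments there
        assert near / len(net) > 2 * (np.pi * 16 / extent.area)

    def test_negative_density_rejected(self, unit_extent):
        with pytest.raises(ValueError, match="density"):
            generate_roads(unit_extent, density=-1.0, n_towns=0, seed=0)

    def test_bad_extent_names_offending_bound(self):
        with pytest.raises(ValueError, match="x_max"):
            Extent(5.0, 0.0, 5.0, 10.0)


class TestGenerateHostTrees:
    @pytest.fixture
    def one_road(self):
        ext = Extent(0, 0, 2, 2)
        road = RoadNetwork(
            segments=[RoadSegment(id="r", vertices=[(0.0, 1.0), (2.0, 1.0)])]
        )
        return ext, road

    def test_zero_intensity_gives_no_trees(self, one_road):
        ext, road = one_road
        assert generate_host_trees(road, ext, 0.0, 5.0, 0.05, 0.02, 2.0, seed=1) == []

    def test_negative_band_rejected(self, one_road):
        ext, road = one_road
        with pytest.raises(ValueError, match="roadside_band"):
            generate_host_trees(road, ext, 1.0, 5.0, -0.1, 0.02, 2.0, seed=1)

    def test_trees_inside_extent_with_distances(self, one_road):
        ext, road = one_road
        trees = generate_host_trees(road, ext, 20.0, 5.0, 0.05, 0.02, 2.0, seed=3)
        line = LineString([(0, 1), (2, 1)])
        for t in trees:
            assert ext.contains(*t.location)
            assert t.dist_to_road == pytest.approx(Point(t.location).distance(line))

    @staticmethod
    def _band_fraction(ext, road, multiplier, seed, band=0.05):
        trees = generate_host_trees(
            road, ext, 30.0, multiplier, band, 0.01, 2.0, seed=seed
        )
        if not trees:
            return None
        n_band = sum(1 for t in trees if t.dist_to_road <= band)
        return n_band / len(trees)

    def test_no_boost_gives_uniform_band_share(self, one_road):
        # multiplier 1: fraction of trees in the roadside band matches its
        # area share, within 3 empirical SE over 100 replicates
        ext, road = one_road
        band_area = (
            LineString([(0, 1), (2, 1)]).buffer(0.05).intersection(box(0, 0, 2, 2)).area
        )
        fracs = np.array(
            [self._band_fraction(ext, road, 1.0, s) for s in range(100)], dtype=float
        )
        se = np.nanstd(fracs, ddof=1) / np.sqrt(np.isfinite(fracs).sum())
        assert abs(np.nanmean(fracs) - band_area / ext.area) <= 3 * se

    def test_roadside_boost_raises_band_density(self, one_road):
        # multiplier 10, band 0.05 km: band density > interior density in
        # >= 95 of 100 replicates (Monte-Carlo sign test)
        ext, road = one_road
        band_area = (
            LineString([(0, 1), (2, 1)]).buffer(0.05).intersection(box(0, 0, 2, 2)).area
        )
        out_area = ext.area - band_area
        wins = 0
        for s in range(100):
            trees = generate_host_trees(road, ext, 30.0, 10.0, 0.05, 0.01, 2.0, seed=s)
            n_band = sum(1 for t in trees if t.dist_to_road <= 0.05)
            n_out = len(trees) - n_band
            if n_band / band_area > n_out / out_area:
                wins += 1
        assert wins >= 95


class TestFrontOccupancy:
    def test_equal_probabilities_give_constant_surface(self, unit_extent):
        occ = make_front_occupancy(unit_extent, 5.0, 2.0, 0.6, 0.6)
        xs = np.linspace(0, 9.9, 25)
        assert np.allclose(occ(xs, xs), 0.6)

    def test_midpoint_value_at_front(self, unit_extent):
        occ = make_front_occupancy(unit_extent, 5.0, 2.0, 1.0, 0.0)
        assert occ(5.0, 0.0) == pytest.approx(0.5)

    def test_zero_width_is_step(self, unit_extent):
        occ = make_front_occupancy(unit_extent, 5.0, 0.0, 0.8, 0.1)
        assert occ(4.0, 0.0) == pytest.approx(0.8)
        assert occ(6.0, 0.0) == pytest.approx(0.1)

    def test_monotone_along_axis(self, unit_extent):
        occ = make_front_occupancy(unit_extent, 5.0, 3.0, 0.9, 0.05)
        xs = np.linspace(0, 10, 101)
        vals = occ(xs, np.zeros_like(xs))
        assert np.all(np.diff(vals) <= 1e-12)

    def test_invalid_probabilities_rejected(self, unit_extent):
        with pytest.raises(ValueError):
            make_front_occupancy(unit_extent, 5.0, 2.0, 0.3, 0.6)  # ahead > behind
        with pytest.raises(ValueError):
            make_front_occupancy(unit_extent, 5.0, 2.0, 1.2, 0.1)


class TestPlaceNests:
    @staticmethod
    def _uniform_trees(extent, n, seed):
        rng = np.random.default_rng(seed)
        return [
            HostTree(location=(x, y), dist_to_road=0.0)
            for x, y in zip(
                rng.uniform(extent.x_min, extent.x_max, n),
                rng.uniform(extent.y_min, extent.y_max, n),
            )
        ]

    def test_zero_occupancy_gives_no_nests(self, unit_extent):
        trees = self._uniform_trees(unit_extent, 50, 0)
        occ = make_front_occupancy(unit_extent, 5.0, 2.0, 0.0, 0.0)
        assert place_nests(trees, occ, 1.0, seed=1) == []

    def test_full_occupancy_keeps_every_tree(self, unit_extent):
        trees = self._uniform_trees(unit_extent, 50, 0)
        occ = make_front_occupancy(unit_extent, 5.0, 2.0, 1.0, 1.0)
        nests = place_nests(trees, occ, 1.0, seed=1)
        assert len(nests) == len(trees)
        assert {n.location for n in nests} == {t.location for t in trees}

    def test_nests_sit_on_trees(self, unit_extent):
        trees = self._uniform_trees(unit_extent, 200, 2)
        occ = make_front_occupancy(unit_extent, 5.0, 2.0, 0.7, 0.2)
        nests = place_nests(trees, occ, 0.5, seed=3)
        locations = {t.location for t in trees}
        assert all(n.location in locations for n in nests)
        assert all(n.n_nests >= 1 for n in nests)

    def test_deterministic_per_seed(self, unit_extent):
        trees = self._uniform_trees(unit_extent, 200, 2)
        occ = make_front_occupancy(unit_extent, 5.0, 2.0, 0.7, 0.2)
        a = place_nests(trees, occ, 0.5, seed=9)
        b = place_nests(trees, occ, 0.5, seed=9)
        assert [(n.location, n.n_nests) for n in a] == [(n.location, n.n_nests) for n in b]

    @pytest.mark.parametrize("aggregation_range", [0.0, 0.8])
    def test_marginal_calibration(self, unit_extent, aggregation_range):
        # thinning calibration: mean nest fraction over 200 seeds recovers
        # the occupancy probability within 3 Monte-Carlo SE
        trees = self._uniform_trees(unit_extent, 500, 7)
        occ = make_front_occupancy(unit_extent, 5.0, 2.0, 0.3, 0.3)
        fracs = np.array(
            [len(place_nests(trees, occ, aggregation_range, seed=s)) / 500 for s in range(200)]
        )
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.3) <= 3 * se

    def test_negative_range_rejected(self, unit_extent):
        occ = make_front_occupancy(unit_extent, 5.0, 2.0, 0.5, 0.1)
        with pytest.raises(ValueError, match="aggregation_range"):
            place_nests(self._uniform_trees(unit_extent, 10, 0), occ, -1.0, seed=0)
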
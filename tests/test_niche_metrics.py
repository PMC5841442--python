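import itertools
import math

import numpy as np
import pytest
from scipy.spatial import Delaunay
from shapely.geometry import Polygon
from shapely.ops import unary_union

from isonicheweb import (
    bayesian_sea,
    category_metrics,
    convex_hull_area,
    ellipse_overlap,
    layman_ranges,
    seac,
    standard_ellipse,
)
from isonicheweb.errors import DegenerateEllipseError, InsufficientDataError
from isonicheweb.niche_metrics import group_points, overlap_percent


class TestLaymanRanges:
    def test_identical_points(self):
        assert layman_ranges([(0.0, 0.0), (0.0, 0.0)]) == (0.0, 0.0)

    def test_simple_ranges(self):
        assert layman_ranges([(0.0, 0.0), (3.0, 4.0)]) == (4.0, 3.0)

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientDataError):
            layman_ranges([(0.0, 0.0)])


class TestConvexHullArea:
    def test_unit_square(self):
        assert convex_hull_area([(0, 0), (1, 0), (1, 1), (0, 1)]) == pytest.approx(1.0)

    def test_collinear_is_zero(self):
        assert convex_hull_area([(0, 0), (1, 1), (2, 2)]) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("n", [4, 7, 12])
    def test_matches_exhaustive_triangulation_oracle(self, seed, n):
        """Hull area equals the union of every triangle over the points."""
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2)) * [3.0, 1.5]
        triangles = [Polygon(pts[list(idx)]) for idx in itertools.combinations(range(n), 3)]
        oracle = unary_union([t for t in triangles if t.area > 0]).area
        assert convex_hull_area(pts) == pytest.approx(oracle, rel=1e-9)

    def test_matches_monte_carlo_integration(self):
        """Area of the hull of 50 points agrees with point-in-hull MC to <0.5%."""
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(50, 2))
        tri = Delaunay(pts)  # independent inclusion test
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        box = np.prod(hi - lo)
        mc = rng.uniform(lo, hi, size=(2_000_000, 2))
        inside = (tri.find_simplex(mc) >= 0).mean()
        assert convex_hull_area(pts) == pytest.approx(inside * box, rel=5e-3)


class TestStandardEllipse:
    def test_four_corner_configuration(self):
        ell = standard_ellipse([(1, 1), (1, -1), (-1, 1), (-1, -1)])
        assert np.allclose(ell.cov, np.diag([4 / 3, 4 / 3]))
        assert ell.sea == pytest.approx(4 * math.pi / 3, rel=1e-12)

    @pytest.mark.parametrize("angle", [0.3, 1.2, 2.5])
    def test_rotation_and_translation_invariance(self, angle, rng):
        pts = rng.normal(size=(40, 2)) @ np.array([[1.5, 0.4], [0.0, 0.7]])
        rot = np.array([[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]])
        moved = pts @ rot.T + np.array([5.0, -3.0])
        assert standard_ellipse(moved).sea == pytest.approx(standard_ellipse(pts).sea, abs=1e-9)
        # TA shares the invariance; NR/CR only the translation part
        assert convex_hull_area(moved) == pytest.approx(convex_hull_area(pts), abs=1e-9)
        shifted = pts + np.array([5.0, -3.0])
        assert layman_ranges(shifted) == pytest.approx(layman_ranges(pts), abs=1e-12)

    def test_large_sample_matches_population_value(self):
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        rng = np.random.default_rng(11)
        pts = rng.multivariate_normal([0, 0], cov, size=100_000)
        expected = math.pi * math.sqrt(np.linalg.det(cov))
        assert standard_ellipse(pts).sea == pytest.approx(expected, rel=0.02)

    def test_one_sd_ellipse_contains_about_39_percent(self):
        cov = np.array([[1.5, -0.3], [-0.3, 0.8]])
        rng = np.random.default_rng(3)
        pts = rng.multivariate_normal([1, 2], cov, size=200_000)
        ell = standard_ellipse(pts)
        centered = pts - ell.centroid
        d2 = np.einsum("ij,jk,ik->i", centered, np.linalg.inv(ell.cov), centered)
        frac = (d2 <= 1.0).mean()
        assert frac == pytest.approx(1 - math.exp(-0.5), abs=0.01)

    def test_degenerate_points_rejected(self):
        with pytest.raises(DegenerateEllipseError):
            standard_ellipse([(0, 0), (1, 1), (2, 2)])


class TestSeac:
    def test_small_sample_factor_two(self):
        assert seac(3.0, 3) == pytest.approx(6.0)

    def test_factor_three_halves(self):
        assert seac(4.189, 4) == pytest.approx(6.283, abs=5e-3)

    def test_asymptotically_uncorrected(self):
        assert seac(1.0, 10**6) == pytest.approx(1.0, abs=1e-5)

    def test_exact_formula(self):
        for n in (3, 5, 17, 100):
            assert seac(2.5, n) == 2.5 * (n - 1) / (n - 2)

    def test_undefined_below_three(self):
        with pytest.raises(InsufficientDataError):
            seac(1.0, 2)


class TestBayesianSea:
    def test_seeded_determinism(self, rng):
        pts = rng.normal(size=(20, 2))
        a = bayesian_sea(pts, n_draws=500, seed=9)
        b = bayesian_sea(pts, n_draws=500, seed=9)
        assert np.array_equal(a, b)

    def test_posterior_median_near_sample_sea(self, rng):
        pts = rng.multivariate_normal([0, 0], [[2.0, 0.3], [0.3, 1.0]], size=30)
        draws = bayesian_sea(pts, n_draws=20_000, seed=1)
        assert np.median(draws) == pytest.approx(standard_ellipse(pts).sea, rel=0.15)

    def test_credible_interval_coverage(self):
        """90% CI covers the true SEA in roughly nominal proportion of runs."""
        cov = np.array([[1.2, 0.4], [0.4, 0.9]])
        true_sea = math.pi * math.sqrt(np.linalg.det(cov))
        rng = np.random.default_rng(77)
        hits = 0
        n_sim = 200
        for i in range(n_sim):
            pts = rng.multivariate_normal([0, 0], cov, size=30)
            draws = bayesian_sea(pts, n_draws=1_500, seed=1000 + i)
            lo, hi = np.quantile(draws, [0.05, 0.95])
            hits += lo <= true_sea <= hi
        assert 0.80 <= hits / n_sim <= 0.97


class TestEllipseOverlap:
    def test_identical_ellipses_full_overlap(self, rng):
        ell = standard_ellipse(rng.normal(size=(25, 2)))
        res = ellipse_overlap(ell, ell)
        assert res.overlap_area == pytest.approx(res.area_a, rel=1e-9)
        assert res.pct_of_a == pytest.approx(100.0) and res.pct_of_b == pytest.approx(100.0)

    def test_distant_ellipses_do_not_overlap(self, rng):
        pts = rng.normal(size=(25, 2))
        far = pts + np.array([1e6, 0.0])
        res = ellipse_overlap(standard_ellipse(pts), standard_ellipse(far))
        assert res.overlap_area == 0.0

    def test_symmetry_and_upper_bound(self, rng):
        a = standard_ellipse(rng.normal(size=(30, 2)) * [2.0, 1.0])
        b = standard_ellipse(rng.normal(size=(30, 2)) + [1.0, 0.5])
        ab = ellipse_overlap(a, b, scale_a=1.2, scale_b=1.1)
        ba = ellipse_overlap(b, a, scale_a=1.1, scale_b=1.2)
        assert ab.overlap_area == pytest.approx(ba.overlap_area, rel=1e-9)
        assert ab.overlap_area <= min(ab.area_a, ab.area_b) + 1e-12

    def test_matches_grid_integration(self):
        """Polygon-clipped overlap equals a 2000x2000 grid integral to <0.5%."""
        rng = np.random.default_rng(5)
        a = standard_ellipse(rng.normal(size=(40, 2)) @ [[1.4, 0.3], [0.0, 0.8]])
        b = standard_ellipse(rng.normal(size=(40, 2)) + [0.8, 0.4])
        res = ellipse_overlap(a, b, vertices=2048)

        lo = np.minimum(a.centroid, b.centroid) - 6.0
        hi = np.maximum(a.centroid, b.centroid) + 6.0
        xs = np.linspace(lo[0], hi[0], 2000)
        ys = np.linspace(lo[1], hi[1], 2000)
        gx, gy = np.meshgrid(xs, ys)
        grid = np.stack([gx.ravel(), gy.ravel()], axis=1)
        cell = (xs[1] - xs[0]) * (ys[1] - ys[0])

        def inside(ell, pts):
            centered = pts - ell.centroid
            d2 = np.einsum("ij,jk,ik->i", centered, np.linalg.inv(ell.cov), centered)
            return d2 <= 1.0

        both = inside(a, grid) & inside(b, grid)
        assert res.overlap_area == pytest.approx(both.sum() * cell, rel=5e-3)

    def test_overlap_percent_rounds_half_up(self):
        assert overlap_percent(0.825, 1.0) == 83
        assert overlap_percent(0.5, 1.0) == 50


class TestCategoryMetrics:
    def test_point_count_is_taxa_not_replicates(self, scenario, dataset):
        groups = group_points(dataset.samples, dataset.category_map)
        n_herb = sum(1 for c in scenario.consumers if c.category.value == "herbivore")
        for site in scenario.sites:
            assert len(groups[("herbivore", site)]) == n_herb

    def test_degraded_site_has_wider_herbivore_carbon_range(self, dataset):
        metrics = category_metrics(dataset.samples, dataset.category_map, sea_draws=0)
        assert metrics[("herbivore", "Bonanza")].cr > metrics[("herbivore", "Limones")].cr

    def test_seac_exceeds_sea(self, dataset):
        metrics = category_metrics(dataset.samples, dataset.category_map, sea_draws=0)
        for m in metrics.values():
            assert m.seac > m.sea
            assert m.nr >= 0 and m.cr >= 0 and m.ta >= 0

    def test_small_group_error_names_group(self, dataset):
        two_taxa = [
            s
            for s in dataset.samples
            if s.taxon in ("herbivore_sp01", "herbivore_sp02") or s.role.value == "source"
        ]
        with pytest.raises(InsufficientDataError, match="herbivore"):
            category_metrics(two_taxa, None, sea_draws=0)
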
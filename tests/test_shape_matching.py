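"""Contour resampling, inner geometry, shape contexts and matching."""

import itertools

import numpy as np
import pytest

from mousetrack import shape_matching as sm
from mousetrack._geometry import rotation_matrix


def dijkstra_oracle(points):
    """Independent inner-distance oracle: visibility graph built with
    shapely covers-predicates, shortest paths via networkx Dijkstra."""
    import networkx as nx
    from shapely.geometry import LineString, Polygon

    poly = Polygon(points)
    n = len(points)
    G = nx.Graph()
    for i in range(n):
        G.add_edge(i, (i + 1) % n,
                   weight=float(np.linalg.norm(points[i] - points[(i + 1) % n])))
    for i, j in itertools.combinations(range(n), 2):
        seg = LineString([points[i], points[j]])
        if poly.covers(seg):
            G.add_edge(i, j, weight=float(np.linalg.norm(points[i] - points[j])))
    dist = dict(nx.all_pairs_dijkstra_path_length(G))
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = dist[i][j]
    return out


class TestResampleContour:
    def test_unit_square_four_corners(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        dense = []
        for k in range(4):
            a, b = square[k], square[(k + 1) % 4]
            for t in np.linspace(0, 1, 25, endpoint=False):
                dense.append(a + t * (b - a))
        c = sm.resample_contour(np.array(dense), 8)
        # corners are among the 8 equally spaced points starting at (0, 0)
        assert np.allclose(c.points[0], [0, 0])
        for corner in square:
            assert np.min(np.linalg.norm(c.points - corner, axis=1)) < 1e-9

    def test_idempotent(self):
        # exact for equal chords; approximate otherwise (re-spacing runs
        # along the new polygon, whose chord lengths vary with curvature)
        ang = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        pts = np.stack([50 * np.cos(ang), 50 * np.sin(ang)], axis=1)
        once = sm.resample_contour(pts, 32)
        twice = sm.resample_contour(once.points, 32)
        assert np.allclose(once.points, twice.points, atol=1e-9)
        rng = np.random.default_rng(0)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 50))
        rough = np.stack([50 * np.cos(ang), 50 * np.sin(ang)], axis=1)
        once = sm.resample_contour(rough, 32)
        twice = sm.resample_contour(once.points, 32)
        spacing = 2 * np.pi * 50 / 32
        assert np.abs(once.points - twice.points).max() < 0.05 * spacing

    def test_circle_equal_spacing(self):
        ang = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        pts = np.stack([50 * np.cos(ang), 50 * np.sin(ang)], axis=1)
        c = sm.resample_contour(pts, 100)
        gaps = np.linalg.norm(np.diff(np.vstack([c.points, c.points[:1]]),
                                      axis=0), axis=1)
        assert gaps.max() / gaps.min() < 1.01

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            sm.resample_contour(np.zeros((20, 2)), 4)


class TestInnerGeometry:
    def test_convex_equals_euclidean(self):
        rng = np.random.default_rng(1)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 16))
        pts = np.stack([40 * np.cos(ang), 40 * np.sin(ang)], axis=1)
        d, _ = sm.inner_geometry(sm.Contour(pts))
        eucl = np.linalg.norm(pts[None] - pts[:, None], axis=2)
        assert np.allclose(d, eucl, atol=1e-9)

    def test_u_shape_goes_around_the_bend(self):
        u = np.array([[0, 0], [10, 0], [10, 10], [8, 10], [8, 2],
                      [2, 2], [2, 10], [0, 10]], dtype=float)
        d, _ = sm.inner_geometry(sm.Contour(u))
        i, j = 3, 6     # the two prong tips
        assert d[i, j] == pytest.approx(22.0)
        assert d[i, j] > np.linalg.norm(u[i] - u[j])

    def test_zero_diagonal_and_symmetry(self):
        rng = np.random.default_rng(2)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 20))
        pts = np.stack([30 * np.cos(ang), 30 * np.sin(ang)], axis=1)
        d, a = sm.inner_geometry(sm.Contour(pts))
        assert np.all(np.diag(d) == 0)
        assert np.allclose(d, d.T)

    def test_matches_dijkstra_oracle(self, random_simple_polygons):
        for pts in random_simple_polygons[:5]:
            d, _ = sm.inner_geometry(sm.Contour(pts))
            oracle = dijkstra_oracle(pts)
            assert np.allclose(d, oracle, rtol=1e-9, atol=1e-9)

    def test_inner_distance_at_least_euclidean(self, random_simple_polygons):
        for pts in random_simple_polygons[:5]:
            d, _ = sm.inner_geometry(sm.Contour(pts))
            eucl = np.linalg.norm(pts[None] - pts[:, None], axis=2)
            assert np.all(d >= eucl - 1e-9)


class TestShapeContext:
    @staticmethod
    def _contour(n=30, seed=3):
        rng = np.random.default_rng(seed)
        ang = np.sort(rng.uniform(0, 2 * np.pi, n))
        rad = 30 + 10 * np.sin(3 * ang)
        return sm.Contour(np.stack([rad * np.cos(ang), rad * np.sin(ang)],
                                   axis=1))

    def test_histograms_count_all_other_points(self):
        c = self._contour()
        desc = sm.shape_context(c)
        assert (desc.histograms.sum(axis=1) == c.n - 1).all()
        assert (desc.histograms >= 0).all()

    def test_scale_invariance(self):
        c = self._contour()
        scaled = sm.Contour(c.points * 2.0)
        a = sm.shape_context(c)
        b = sm.shape_context(scaled)
        assert np.array_equal(a.histograms, b.histograms)

    def test_rotation_and_translation_invariance(self):
        c = self._contour()
        R = rotation_matrix(57.0)
        moved = sm.Contour(c.points @ R.T + np.array([11.0, -7.0]))
        a = sm.shape_context(c)
        b = sm.shape_context(moved)
        assert np.array_equal(a.histograms, b.histograms)

    def test_small_polygon_matches_brute_force_binning(self):
        pts = np.array([[0, 0], [10, 0], [13, 8], [5, 14], [-3, 8]],
                       dtype=float)
        c = sm.Contour(pts)
        n_r, n_theta = 2, 4
        dist, ang = sm.inner_geometry(c)
        desc = sm.shape_context(c, n_r=n_r, n_theta=n_theta)
        # brute-force bin assignment
        off = ~np.eye(5, dtype=bool)
        mean_d = dist[off].mean()
        redges = np.logspace(np.log10(sm.R_INNER), np.log10(sm.R_OUTER),
                             n_r + 1)
        expected = np.zeros((5, n_r * n_theta), dtype=int)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                r = dist[i, j] / mean_d
                rb = 0
                for k in range(n_r):
                    if r > redges[k + 1] and k < n_r - 1:
                        rb = k + 1
                tb = int((ang[i, j] + 180.0) // (360.0 / n_theta))
                tb = min(max(tb, 0), n_theta - 1)
                expected[i, rb * n_theta + tb] += 1
        assert np.array_equal(desc.histograms, expected)


class TestChi2Cost:
    def test_identical_histograms_zero(self):
        h = np.array([3, 1, 0, 5])
        assert sm.chi2_cost(h, h) == 0.0

    def test_disjoint_unit_histograms(self):
        assert sm.chi2_cost(np.array([1, 0]), np.array([0, 1])) == \
            pytest.approx(1.0)

    def test_symmetric_on_random_histograms(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.integers(0, 5, 12)
            b = rng.integers(0, 5, 12)
            assert sm.chi2_cost(a, b) == pytest.approx(sm.chi2_cost(b, a))

    def test_empty_bins_contribute_zero(self):
        a = np.array([0, 0, 2])
        b = np.array([0, 1, 2])
        assert sm.chi2_cost(a, b) == pytest.approx(0.5)


class TestMatching:
    def test_self_match_is_identity_with_zero_cost(self):
        rng = np.random.default_rng(5)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 24))
        pts = np.stack([40 * np.cos(ang), 40 * np.sin(ang)], axis=1)
        desc = sm.shape_context(sm.Contour(pts))
        m = sm.match_shapes(desc, desc)
        assert m.total_cost == 0.0
        assert np.array_equal(m.permutation, np.arange(24))

    def test_cyclic_shift_recovered(self):
        rng = np.random.default_rng(6)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 20))
        rad = 30 + 8 * np.sin(2 * ang)
        pts = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)
        shift = 7
        shifted = np.roll(pts, shift, axis=0)
        a = sm.shape_context(sm.Contour(shifted))
        b = sm.shape_context(sm.Contour(pts))
        m = sm.match_shapes(a, b)
        assert m.total_cost == pytest.approx(0.0, abs=1e-12)
        assert np.array_equal(m.permutation,
                              (np.arange(20) - shift) % 20)

    def test_assignment_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(3, 8))
            cost = rng.uniform(0, 10, (n, n))
            perm, H = sm.optimal_assignment(cost)
            brute = min(sum(cost[i, p[i]] for i in range(n))
                        for p in itertools.permutations(range(n)))
            assert H == pytest.approx(brute, rel=1e-12)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sm.optimal_assignment(np.zeros((3, 4)))

    def test_rigid_transform_invariance_of_total_cost(self):
        rng = np.random.default_rng(8)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 30))
        rad = 30 + 10 * np.sin(2 * ang) + 4 * np.cos(5 * ang)
        pts = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)
        moved = pts @ rotation_matrix(123.0).T + np.array([40.0, -20.0])
        a = sm.shape_context(sm.Contour(pts))
        b = sm.shape_context(sm.Contour(moved))
        assert sm.match_shapes(a, b).total_cost == pytest.approx(0.0,
                                                                 abs=1e-12)
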
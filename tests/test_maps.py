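"""Delaunay neighbour graphs, packing/proliferation maps, pooling, Voronoi tiles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mesomap import (
    CentroidField,
    RegionMask,
    RigidTransform2D,
    align_and_pool,
    assign_labels,
    compare_groups,
    delaunay_neighbors,
    interior_points,
    double_corona_index,
    packing_map,
    regional_mean,
    voronoi_heatmap,
)
from mesomap.synth import SyntheticTissueSpec, generate_centroid_field


def brute_force_delaunay_edges(pts: np.ndarray, eps: float = 1e-9) -> set[tuple[int, int]]:
    """Independent oracle: a triangle is Delaunay iff its circumcircle is empty."""
    n = len(pts)
    edges: set[tuple[int, int]] = set()
    for i, j, k in itertools.combinations(range(n), 3):
        ax, ay = pts[i]
        bx, by = pts[j]
        cx, cy = pts[k]
        d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            continue  # collinear triple
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
              + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
              + (cx**2 + cy**2) * (bx - ax)) / d
        r2 = (ax - ux) ** 2 + (ay - uy) ** 2
        others = np.delete(np.arange(n), [i, j, k])
        d2 = (pts[others, 0] - ux) ** 2 + (pts[others, 1] - uy) ** 2
        if np.all(d2 > r2 * (1 - eps)):
            edges |= {tuple(sorted(e)) for e in ((i, j), (j, k), (i, k))}
    return edges


def triangular_lattice(rows: int, cols: int, d: float = 10.0) -> np.ndarray:
    pts = []
    for r in range(rows):
        for c in range(cols):
            pts.append((c * d + (r % 2) * d / 2, r * d * np.sqrt(3) / 2))
    return np.array(pts)


class TestDelaunayNeighbors:
    def test_triangle_fixture(self):
        pts = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 3.0]])
        g = delaunay_neighbors(pts)
        assert g.adjacency == [{1, 2}, {0, 2}, {0, 1}]
        assert g.edge_length(0, 1) == pytest.approx(4.0)
        assert g.edge_length(0, 2) == pytest.approx(3.0)
        assert g.edge_length(1, 2) == pytest.approx(5.0)
        assert g.hull_flags.all()

    def test_four_point_fixture_has_five_edges(self):
        pts = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 3.0], [5.0, 5.0]])
        g = delaunay_neighbors(pts)
        edges = set(g.edge_lengths)
        assert len(edges) == 5
        assert edges == brute_force_delaunay_edges(pts)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_empty_circumcircle_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, size=(30, 2))
        g = delaunay_neighbors(pts)
        assert set(g.edge_lengths) == brute_force_delaunay_edges(pts)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            delaunay_neighbors(np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValueError):
            delaunay_neighbors(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]))

    def test_adjacency_symmetric_irreflexive(self):
        rng = np.random.default_rng(3)
        g = delaunay_neighbors(rng.uniform(0, 50, size=(40, 2)))
        for i, nbrs in enumerate(g.adjacency):
            assert i not in nbrs
            for j in nbrs:
                assert i in g.adjacency[j]


class TestPackingMap:
    def test_regular_lattice_interior_equals_spacing(self):
        pts = triangular_lattice(9, 9, d=10.0)
        g = delaunay_neighbors(pts)
        p = packing_map(g)
        interior = interior_points(g, depth=1)
        assert np.allclose(p.raw_mean_edge[interior], 10.0, atol=1e-9)
        assert np.allclose(p.smoothed_mean_edge[interior], 10.0, atol=1e-9)

    def test_homogeneity_under_scaling(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, size=(60, 2))
        p1 = packing_map(delaunay_neighbors(pts))
        p2 = packing_map(delaunay_neighbors(2.0 * pts))
        assert np.allclose(p2.raw_mean_edge, 2 * p1.raw_mean_edge)
        assert np.allclose(p2.smoothed_mean_edge, 2 * p1.smoothed_mean_edge)

    def test_recovers_imposed_spacing_gradient(self):
        # spacing ramp 8 -> 14 μm across x; smoothed map should track ground truth
        spec = SyntheticTissueSpec(
            domain_polygon=((0, 0), (400, 0), (400, 200), (0, 200)),
            target_spacing_field=lambda x, y: 8.0 + 6.0 * x / 400.0,
            seed=4,
        )
        field, truth = generate_centroid_field(spec)
        g = delaunay_neighbors(field)
        p = packing_map(g)
        interior = interior_points(g)
        r = np.corrcoef(p.smoothed_mean_edge[interior], truth.local_spacing[interior])[0, 1]
        assert r >= 0.8

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(angle=st.floats(-180, 180), tx=st.floats(-50, 50), ty=st.floats(-50, 50))
    def test_rigid_motion_invariance(self, angle, tx, ty):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 80, size=(40, 2))
        moved = RigidTransform2D(angle, tx, ty).apply(pts)
        p1 = packing_map(delaunay_neighbors(pts))
        p2 = packing_map(delaunay_neighbors(moved))
        assert np.allclose(np.sort(p1.smoothed_mean_edge), np.sort(p2.smoothed_mean_edge), atol=1e-6)


class TestDoubleCoronaIndex:
    def hexagon_with_centre(self):
        ang = np.deg2rad(np.arange(0, 360, 60))
        pts = np.vstack([[0.0, 0.0], np.c_[np.cos(ang), np.sin(ang)] * 10])
        return pts

    @pytest.mark.parametrize("value", [0.0, 1.0])
    def test_constant_labels_give_constant_index(self, value):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 60, size=(50, 2))
        g = delaunay_neighbors(pts)
        m = double_corona_index(g, np.full(50, bool(value)))
        assert np.all(m.local_index == value)

    def test_hexagon_fixture_hand_enumeration(self):
        # centre labelled only: every double corona covers all 7 points -> L = 1/7
        pts = self.hexagon_with_centre()
        flags = np.zeros(7, dtype=bool)
        flags[0] = True
        g = delaunay_neighbors(pts)
        m = double_corona_index(g, flags)
        assert np.allclose(m.local_index, 1 / 7)
        assert np.all(m.corona_size == 7)

    def test_step_probability_field_recovered(self):
        # p = 0.1 on the left half, 0.6 on the right; mean L per half within 0.05
        spec = SyntheticTissueSpec(
            domain_polygon=((0, 0), (720, 0), (720, 400), (0, 400)),
            target_spacing_field=10.0,
            label_prob_field=lambda x, y: np.where(x < 360, 0.1, 0.6),
            seed=8,
        )
        field, truth = generate_centroid_field(spec)
        assert len(field) > 1800
        g = delaunay_neighbors(field)
        m = double_corona_index(g, field.label_flags)
        # stay clear of the step and the hull so coronas do not straddle
        left = (field.x > 30) & (field.x < 330) & (field.y > 30) & (field.y < 370)
        right = (field.x > 390) & (field.x < 690) & (field.y > 30) & (field.y < 370)
        assert abs(m.local_index[left].mean() - 0.1) < 0.05
        assert abs(m.local_index[right].mean() - 0.6) < 0.05

    def test_missing_flags_rejected(self):
        g = delaunay_neighbors(np.random.default_rng(0).uniform(0, 10, (10, 2)))
        with pytest.raises(ValueError):
            double_corona_index(g, None)

    def test_index_invariant_under_point_permutation(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 60, size=(40, 2))
        flags = rng.random(40) < 0.4
        perm = rng.permutation(40)
        m1 = double_corona_index(delaunay_neighbors(pts), flags)
        m2 = double_corona_index(delaunay_neighbors(pts[perm]), flags[perm])
        assert np.allclose(m1.local_index[perm], m2.local_index)


class TestAlignAndPool:
    def test_single_identity_section_is_identity(self):
        rng = np.random.default_rng(2)
        f = CentroidField(rng.uniform(0, 50, (20, 2)), rng.random(20) < 0.5)
        pooled = align_and_pool([(f, RigidTransform2D())])
        assert np.array_equal(pooled.points, f.points)
        assert np.array_equal(pooled.label_flags, f.label_flags)

    def test_inverse_transform_twins_are_merged(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 50, (30, 2))
        t = RigidTransform2D(30.0, 12.0, -7.0)
        raw = CentroidField(t.inverse().apply(pts))
        pooled = align_and_pool([(CentroidField(pts), RigidTransform2D()), (raw, t)])
        assert len(pooled) == 30  # every point found its twin and merged

    def test_three_sections_reduce_spacing_by_sqrt3(self):
        # pooling triples density, so mean spacing shrinks ~1/sqrt(3)
        ratios = []
        for seed in range(20):
            spec = SyntheticTissueSpec(domain_polygon=((0, 0), (150, 0), (150, 150), (0, 150)),
                                       target_spacing_field=10.0, n_sections=3, seed=seed)
            from mesomap import generate_section_stack

            stack = generate_section_stack(spec)
            pooled = align_and_pool(stack)
            g1 = delaunay_neighbors(stack[0][0])
            gp = delaunay_neighbors(pooled)
            p1 = packing_map(g1)
            pp = packing_map(gp)
            ratios.append(np.median(pp.smoothed_mean_edge[~gp.hull_flags])
                          / np.median(p1.smoothed_mean_edge[~g1.hull_flags]))
        assert np.mean(ratios) == pytest.approx(1 / np.sqrt(3), rel=0.12)


class TestVoronoiHeatmap:
    def test_tiles_partition_domain(self):
        rng = np.random.default_rng(4)
        field = CentroidField(rng.uniform(5, 95, (40, 2)))
        domain = RegionMask([(0, 0), (100, 0), (100, 100), (0, 100)], "square")
        vmap = voronoi_heatmap(field, np.ones(40), domain=domain)
        total = sum(t.area for t in vmap.tiles)
        assert total == pytest.approx(100 * 100, rel=1e-6)
        assert len(set(np.round(vmap.clamped, 12))) == 1

    def test_tile_assignment_matches_nearest_point(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(5, 95, (25, 2))
        field = CentroidField(pts)
        values = np.where(pts[:, 0] < 50, 1.0, 2.0)
        domain = RegionMask([(0, 0), (100, 0), (100, 100), (0, 100)])
        vmap = voronoi_heatmap(field, values, domain=domain, colour_range=(1.0, 2.0))
        assert set(vmap.clamped) == {1.0, 2.0}
        from scipy.spatial import cKDTree

        tree = cKDTree(pts)
        for tile, v in zip(vmap.tiles, vmap.values):
            if tile.is_empty:
                continue
            rep = tile.representative_point()
            _, nearest = tree.query([rep.x, rep.y])
            assert values[nearest] == v

    def test_values_clamped_to_colour_range(self):
        rng = np.random.default_rng(7)
        field = CentroidField(rng.uniform(0, 50, (10, 2)))
        values = np.full(10, 20.0)
        vmap = voronoi_heatmap(field, values, colour_range=(7.0, 14.0))
        assert np.all(vmap.clamped == 14.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            voronoimap = voronoi_heatmap(CentroidField(np.array([[0, 0], [1, 0], [0, 1]])), np.ones(3))


class TestRegionalMeanAndGroups:
    def test_constant_values_give_mean_sd_zero(self):
        rng = np.random.default_rng(8)
        field = CentroidField(rng.uniform(0, 10, (30, 2)))
        region = RegionMask([(-1, -1), (11, -1), (11, 11), (-1, 11)], "all")
        st_ = regional_mean(np.full(30, 5.0), region, field)
        assert (st_.mean, st_.sd, st_.n) == (5.0, 0.0, 30)

    def test_disjoint_region_raises_named_error(self):
        field = CentroidField(np.random.default_rng(9).uniform(0, 10, (10, 2)))
        region = RegionMask([(100, 100), (110, 100), (110, 110), (100, 110)], "far")
        with pytest.raises(ValueError, match="far"):
            regional_mean(np.ones(10), region, field)

    def test_half_plane_mean_matches_step_probability(self):
        spec = SyntheticTissueSpec(
            domain_polygon=((0, 0), (720, 0), (720, 400), (0, 400)),
            target_spacing_field=10.0,
            label_prob_field=lambda x, y: np.where(x < 360, 0.1, 0.6),
            seed=8,
        )
        field, _ = generate_centroid_field(spec)
        g = delaunay_neighbors(field)
        m = double_corona_index(g, field.label_flags)
        region = RegionMask([(390, 30), (690, 30), (690, 370), (390, 370)], "right")
        st_ = regional_mean(m.local_index, region, field)
        assert abs(st_.mean - 0.6) < 0.05

    def test_identical_groups_p_one(self):
        vals = np.arange(10.0)
        assert compare_groups(vals, vals) == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 20)
        b = rng.normal(5, 1, 20)
        assert compare_groups(a, b) < 0.001

    def test_symmetric_in_argument_order(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 2, 12)
        assert compare_groups(a, b) == pytest.approx(compare_groups(b, a))
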
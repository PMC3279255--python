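"""Segmentation, triangulation, filtering, meshing and view merging."""

import numpy as np
import pytest
from scipy.optimize import minimize

from codedlight.calibration import Ray
from codedlight.patterns import PixelCodeMap
from codedlight.reconstruction import (
    PointCloud,
    build_point_cloud,
    filter_isolated,
    merge_views,
    mesh_points,
    mesh_regions,
    rotation_about_z,
    segment_green,
    smooth_cloud,
    triangulate_rays,
)
from codedlight.traits import surface_area


def make_cloud(points, labels=None):
    n = len(points)
    return PointCloud(
        points=np.asarray(points, float),
        source_pixel=np.zeros((n, 2)),
        ray_gap=np.zeros(n),
        view=np.zeros(n),
        labels=np.full(n, -1) if labels is None else np.asarray(labels),
    )


class TestSegmentGreen:
    def test_pure_green_true_gray_false(self):
        img = np.array([[[0, 255, 0], [128, 128, 128]]], dtype=np.uint8)
        mask = segment_green(img)
        assert mask[0, 0] and not mask[0, 1]

    def test_unattainable_threshold_gives_empty_mask(self):
        img = np.full((4, 4, 3), 255, dtype=np.uint8)
        assert not segment_green(img, threshold=511).any()

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            segment_green(np.zeros((4, 4)))

    def test_matches_renderer_leaf_mask(self, flat_leaf_render):
        scene, captures, truth = flat_leaf_render
        mask = segment_green(captures.rgb)
        assert np.array_equal(mask, truth.leaf_id >= 0)


class TestTriangulateRays:
    def test_exact_intersection(self):
        target = np.array([10.0, 20.0, 300.0])
        a = Ray(origin=[0.0, 0.0, 0.0], direction=target)
        b = Ray(origin=[100.0, 0.0, 0.0], direction=target - [100.0, 0.0, 0.0])
        point, gap = triangulate_rays(a, b)
        assert np.allclose(point, target, atol=1e-9)
        assert gap < 1e-9

    def test_skew_rays_match_numeric_least_squares_oracle(self):
        a = Ray(origin=[0.0, 0.0, 0.0], direction=[0.0, 0.0, 1.0])
        b = Ray(origin=[50.0, 2.0, 0.0], direction=[-1.0, 0.0, 1.0])
        point, gap = triangulate_rays(a, b)

        def line_dist2(p, ray):
            d = np.asarray(ray.direction)
            w = p - ray.origin
            return float(w @ w - (w @ d) ** 2)

        res = minimize(
            lambda p: line_dist2(p, a) + line_dist2(p, b),
            x0=np.array([10.0, 1.0, 30.0]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000},
        )
        assert np.allclose(point, res.x, atol=1e-4)
        assert np.isclose(gap, 2.0, atol=1e-9)  # offset is purely along y

    def test_symmetric_in_arguments(self):
        a = Ray(origin=[0.0, 0.0, 0.0], direction=[0.1, 0.2, 1.0])
        b = Ray(origin=[30.0, -10.0, 5.0], direction=[-0.2, 0.1, 1.0])
        p1, g1 = triangulate_rays(a, b)
        p2, g2 = triangulate_rays(b, a)
        assert np.allclose(p1, p2) and np.isclose(g1, g2)

    def test_near_parallel_rays_rejected(self):
        a = Ray(origin=[0.0, 0.0, 0.0], direction=[0.0, 0.0, 1.0])
        b = Ray(origin=[10.0, 0.0, 0.0], direction=[0.0, 1e-9, 1.0])
        with pytest.raises(ValueError, match="parallel"):
            triangulate_rays(a, b)


class TestBuildPointCloud:
    def test_planar_leaf_points_lie_on_the_plane(self, flat_leaf_render, mats_small):
        from codedlight.patterns import binarize_captures, decode_projector_coords

        scene, captures, truth = flat_leaf_render
        mask = segment_green(captures.rgb)
        bits, reliable = binarize_captures(
            captures.frames, captures.lit_reference, captures.dark_reference
        )
        codes = decode_projector_coords(bits, captures.spec, mask & reliable)
        cloud = build_point_cloud(codes, mats_small["ref_cam"], mats_small["projector"])
        dist = np.abs(cloud.points[:, 2] - 80.0)
        assert (dist < 0.5).mean() >= 0.99

    def test_empty_mask_gives_empty_cloud(self, mats_small):
        h, w = 16, 16
        codes = PixelCodeMap(
            bits=np.zeros((48, h, w), np.uint8),
            valid_mask=np.zeros((h, w), bool),
            u=np.full((h, w), -1, np.int32),
            v=np.full((h, w), -1, np.int32),
        )
        cloud = build_point_cloud(codes, mats_small["ref_cam"], mats_small["projector"])
        assert len(cloud) == 0

    def test_corrupted_code_exceeds_gap_and_is_discarded(self, flat_leaf_render, mats_small):
        from codedlight.patterns import binarize_captures, decode_projector_coords

        scene, captures, truth = flat_leaf_render
        mask = segment_green(captures.rgb)
        bits, reliable = binarize_captures(
            captures.frames, captures.lit_reference, captures.dark_reference
        )
        codes = decode_projector_coords(bits, captures.spec, mask & reliable)
        rows, cols = np.nonzero(codes.valid_mask)
        r, c = rows[len(rows) // 2], cols[len(rows) // 2]
        clean = build_point_cloud(codes, mats_small["ref_cam"], mats_small["projector"])
        codes.u[r, c] += 200  # one wildly wrong projector column
        corrupt = build_point_cloud(codes, mats_small["ref_cam"], mats_small["projector"])
        assert len(corrupt) == len(clean) - 1
        assert not np.any((corrupt.source_pixel == [c, r]).all(axis=1))

    def test_device_tag_collision_rejected(self, mats_small):
        codes = PixelCodeMap(
            bits=np.zeros((48, 4, 4), np.uint8),
            valid_mask=np.zeros((4, 4), bool),
            u=np.full((4, 4), -1, np.int32),
            v=np.full((4, 4), -1, np.int32),
        )
        with pytest.raises(ValueError, match="device"):
            build_point_cloud(codes, mats_small["ref_cam"], mats_small["ref_cam"])


class TestFilterIsolated:
    def test_cluster_survives_outlier_removed(self):
        rng = np.random.default_rng(0)
        cluster = rng.uniform(-0.5, 0.5, size=(12, 3))
        outlier = np.array([[100.0, 0.0, 0.0]])
        cloud = make_cloud(np.vstack([cluster, outlier]))
        kept = filter_isolated(cloud, radius=2.5, min_neighbors=10)
        assert len(kept) == 12
        assert np.abs(kept.points).max() < 1.0

    def test_matches_brute_force_neighbor_counts(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 20, size=(150, 3))
        cloud = make_cloud(pts)
        kept = filter_isolated(cloud, radius=3.0, min_neighbors=4)
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        counts = (d <= 3.0).sum(axis=1) - 1
        expected = pts[counts >= 4]
        assert np.array_equal(kept.points, expected)

    def test_empty_cloud_and_zero_neighbors_are_identities(self):
        assert len(filter_isolated(PointCloud.empty())) == 0
        cloud = make_cloud(np.random.default_rng(2).random((5, 3)) * 100)
        assert len(filter_isolated(cloud, min_neighbors=0)) == 5

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 30, size=(120, 3))
        cloud = make_cloud(pts)
        kept = filter_isolated(cloud, radius=4.0, min_neighbors=3)
        R = rotation_about_z(37.0)
        moved = make_cloud(pts @ R.T + [5.0, -2.0, 11.0])
        kept_moved = filter_isolated(moved, radius=4.0, min_neighbors=3)
        assert len(kept) == len(kept_moved)
        assert np.allclose(kept.points @ R.T + [5.0, -2.0, 11.0], kept_moved.points)


class TestSmoothCloud:
    def test_reduces_out_of_plane_jitter(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(0, 30, size=(800, 2))
        z = rng.normal(0, 0.3, 800)
        cloud = make_cloud(np.column_stack([xy, z]))
        smoothed = smooth_cloud(cloud, radius=2.0)
        assert len(smoothed) == 800
        assert np.abs(smoothed.points[:, 2]).std() < 0.5 * z.std()

    def test_zero_radius_is_identity(self):
        cloud = make_cloud(np.random.default_rng(5).random((20, 3)))
        out = smooth_cloud(cloud, radius=0.0)
        assert np.array_equal(out.points, cloud.points)


class TestMeshing:
    def test_square_grid_gives_two_triangles_of_known_area(self):
        pts = np.array([[0, 0, 5.0], [10, 0, 5.0], [0, 10, 5.0], [10, 10, 5.0]])
        cloud = PointCloud(
            points=pts,
            source_pixel=pts[:, :2],
            ray_gap=np.zeros(4),
            view=np.zeros(4),
            labels=np.zeros(4, int),
        )
        mesh = mesh_points(cloud, max_edge=20.0)
        assert mesh.faces.shape[0] == 2
        assert np.isclose(surface_area(mesh), 1.0)  # 100 mm^2 = 1 cm^2

    def test_dense_flat_patch_area_within_two_percent(self):
        rng = np.random.default_rng(6)
        xy = rng.uniform(0, 40, size=(4000, 2))
        pts = np.column_stack([xy, np.full(4000, 7.0)])
        cloud = PointCloud(
            points=pts,
            source_pixel=xy,
            ray_gap=np.zeros(4000),
            view=np.zeros(4000),
            labels=np.zeros(4000, int),
        )
        mesh = mesh_points(cloud, max_edge=10.0)
        assert abs(surface_area(mesh) - 16.0) / 16.0 < 0.02

    def test_distant_patches_are_not_bridged(self):
        rng = np.random.default_rng(7)
        a = np.column_stack([rng.uniform(0, 10, (200, 2)), np.zeros(200)])
        b = a + [50.0, 0.0, 0.0]
        pts = np.vstack([a, b])
        cloud = PointCloud(
            points=pts,
            source_pixel=pts[:, :2],
            ray_gap=np.zeros(400),
            view=np.zeros(400),
            labels=np.zeros(400, int),
        )
        mesh = mesh_points(cloud, max_edge=5.0)
        x_of_faces = mesh.vertices[mesh.faces][:, :, 0]
        spans_gap = (x_of_faces.min(axis=1) < 15) & (x_of_faces.max(axis=1) > 45)
        assert not spans_gap.any()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            mesh_points(make_cloud(np.zeros((2, 3))))

    def test_area_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(8)
        xy = rng.uniform(0, 20, size=(500, 2))
        pts = np.column_stack([xy, 0.05 * rng.standard_normal(500)])
        cloud = PointCloud(
            points=pts,
            source_pixel=xy,
            ray_gap=np.zeros(500),
            view=np.zeros(500),
            labels=np.zeros(500, int),
        )
        mesh = mesh_points(cloud, max_edge=8.0)
        a0 = surface_area(mesh)
        R = rotation_about_z(63.0)
        mesh.vertices = mesh.vertices @ R.T + [100.0, 50.0, -20.0]
        assert np.isclose(surface_area(mesh), a0, rtol=1e-12)

    def test_tightening_max_edge_never_grows_area(self):
        rng = np.random.default_rng(9)
        xy = rng.uniform(0, 25, size=(600, 2))
        pts = np.column_stack([xy, np.zeros(600)])
        cloud = PointCloud(
            points=pts,
            source_pixel=xy,
            ray_gap=np.zeros(600),
            view=np.zeros(600),
            labels=np.zeros(600, int),
        )
        areas = [surface_area(mesh_points(cloud, max_edge=e)) for e in (10.0, 5.0, 2.0)]
        assert areas[0] >= areas[1] >= areas[2]

    def test_mesh_regions_separates_labels(self):
        rng = np.random.default_rng(10)
        a = np.column_stack([rng.uniform(0, 10, (150, 2)), np.zeros(150)])
        b = np.column_stack([rng.uniform(0, 10, (150, 2)), np.full(150, 30.0)])
        cloud = make_cloud(np.vstack([a, b]), labels=np.r_[np.zeros(150), np.ones(150)])
        mesh = mesh_regions(cloud, max_edge=5.0)
        z_of_faces = mesh.vertices[mesh.faces][:, :, 2]
        assert np.all((z_of_faces.max(axis=1) < 1) | (z_of_faces.min(axis=1) > 29))


class TestMergeViews:
    def test_merge_with_empty_is_identity(self):
        cloud = make_cloud(np.random.default_rng(11).random((10, 3)))
        merged = merge_views(cloud, PointCloud.empty())
        assert np.array_equal(merged.points, cloud.points)

    def test_full_turn_is_identity(self):
        cloud = make_cloud(np.random.default_rng(12).random((10, 3)) * 100)
        merged = merge_views(PointCloud.empty(), cloud, rotation_deg=360.0)
        assert np.allclose(merged.points, cloud.points, atol=1e-9)

    def test_provenance_is_preserved(self):
        a = make_cloud([[1.0, 0, 0]], labels=[3])
        b = make_cloud([[0, 1.0, 0]], labels=[5])
        b.view[:] = 180.0
        merged = merge_views(a, b, rotation_deg=180.0)
        assert list(merged.labels) == [3, 5]
        assert list(merged.view) == [0.0, 180.0]
        assert np.allclose(merged.points[1], [0, -1.0, 0])
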
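"""C2C/C2M distance fields, summaries, histograms, heat maps, compare()."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import morphodist as md


def oracle_point_triangle(p, a, b, c):
    """Independent exact point-triangle distance: orthogonal foot if its
    barycentric coordinates are non-negative, else the best of the three
    clamped segment projections."""
    n = np.cross(b - a, c - a)
    candidates = []
    nn = n @ n
    if nn > 0:
        foot = p - ((p - a) @ n) / nn * n
        # barycentric via 2x2 solve
        v0, v1, v2 = b - a, c - a, foot - a
        d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
        d20, d21 = v2 @ v0, v2 @ v1
        den = d00 * d11 - d01 * d01
        if den != 0:
            v = (d11 * d20 - d01 * d21) / den
            w = (d00 * d21 - d01 * d20) / den
            if v >= 0 and w >= 0 and v + w <= 1:
                candidates.append(np.linalg.norm(p - foot))
    for s, e in ((a, b), (b, c), (c, a)):
        d = e - s
        t = np.clip((p - s) @ d / (d @ d), 0.0, 1.0)
        candidates.append(np.linalg.norm(p - (s + t * d)))
    return min(candidates)


class TestC2C:
    def test_self_distance_is_zero(self, rng):
        cloud = md.PointCloud(rng.normal(size=(50, 3)))
        field = md.c2c(cloud, cloud)
        assert field.mode == "C2C"
        np.testing.assert_array_equal(field.distances, 0.0)

    def test_three_four_five(self):
        field = md.c2c(
            md.PointCloud([[0, 0, 0]]), md.PointCloud([[3, 4, 0], [10, 0, 0]])
        )
        assert field.distances[0] == pytest.approx(5.0)

    def test_matches_brute_force(self, rng):
        a = md.PointCloud(rng.normal(size=(100, 3)))
        b = md.PointCloud(rng.normal(size=(80, 3)))
        field = md.c2c(a, b)
        brute = np.sqrt(
            ((a.points[:, None] - b.points[None]) ** 2).sum(-1)
        ).min(axis=1)
        np.testing.assert_array_equal(field.distances, brute)

    def test_not_symmetric_in_general(self):
        a = md.PointCloud([[0, 0, 0], [100, 0, 0]])
        b = md.PointCloud([[0, 0, 0]])
        ab = md.summarize(md.c2c(a, b)).mean
        ba = md.summarize(md.c2c(b, a)).mean
        assert ab != ba

    def test_empty_cloud_rejected(self):
        with pytest.raises(md.ValidationError):
            md.c2c(md.PointCloud(np.zeros((0, 3))), md.PointCloud([[0, 0, 0]]))


class TestC2M:
    TRI = md.TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])

    def test_perpendicular_foot_inside_face(self):
        field = md.c2m(md.PointCloud([[0.2, 0.2, 1.0]]), self.TRI)
        assert field.distances[0] == pytest.approx(1.0)

    def test_closest_at_vertex(self):
        field = md.c2m(md.PointCloud([[2, 0, 0]]), self.TRI)
        assert field.distances[0] == pytest.approx(1.0)

    def test_closest_on_edge(self):
        field = md.c2m(md.PointCloud([[0.5, -1.0, 0.0]]), self.TRI)
        assert field.distances[0] == pytest.approx(1.0)

    def test_vertices_of_mesh_have_zero_distance(self, claw):
        field = md.c2m(md.mesh_to_cloud(claw), claw)
        np.testing.assert_array_equal(field.distances, 0.0)

    def test_matches_independent_oracle(self, claw, rng):
        pts = rng.normal(size=(40, 3)) * 10
        field = md.c2m(md.PointCloud(pts), claw)
        tri = claw.triangles()
        for i, p in enumerate(pts):
            expected = min(oracle_point_triangle(p, *t) for t in tri)
            assert field.distances[i] == pytest.approx(expected, abs=1e-12)

    def test_never_exceeds_c2c_to_vertices(self, claw, rng):
        pts = md.PointCloud(rng.normal(size=(60, 3)) * 8)
        dm = md.c2m(pts, claw).distances
        dc = md.c2c(pts, md.mesh_to_cloud(claw)).distances
        assert np.all(dm <= dc + 1e-12)

    def test_faceless_reference_rejected(self):
        with pytest.raises(md.ValidationError):
            md.c2m(md.PointCloud([[0, 0, 0]]),
                   md.TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], []))

    def test_rigid_motion_invariance(self, claw, rng):
        pts = md.PointCloud(rng.normal(size=(30, 3)) * 5)
        base = md.c2m(pts, claw).distances
        motion = md.SimilarityTransform(
            1.0, Rotation.from_euler("xyz", [0.4, 0.1, -0.3]).as_matrix(), [7, -2, 3]
        )
        moved = md.c2m(
            md.apply_transform(pts, motion), md.apply_transform(claw, motion)
        ).distances
        np.testing.assert_allclose(moved, base, atol=1e-9)


class TestSummarize:
    def test_constant_field(self):
        field = md.DistanceField(np.full(10, 3.5), "C2C")
        s = md.summarize(field)
        assert (s.mean, s.sd, s.min, s.max, s.n) == (3.5, 0.0, 3.5, 3.5, 10)

    def test_two_values_sample_sd(self):
        s = md.summarize(md.DistanceField([0.0, 2.0], "C2C"))
        assert s.mean == pytest.approx(1.0)
        assert s.sd == pytest.approx(np.sqrt(2.0))
        assert s.directed_hausdorff == 2.0


class TestHistogram:
    def test_single_value_one_nonzero_bin(self):
        edges, counts = md.histogram(md.DistanceField([2.0, 2.0], "C2C"), bin_count=8)
        assert counts.sum() == 2
        assert (counts > 0).sum() == 1

    def test_counts_sum_to_n(self, rng):
        field = md.DistanceField(rng.random(1000), "C2C")
        edges, counts = md.histogram(field, bin_count=256)
        assert counts.sum() == field.n
        assert len(edges) == 257

    def test_uniform_field_is_flat_within_binomial_bound(self, rng):
        n, bins = 100_000, 10
        field = md.DistanceField(rng.random(n), "C2C")
        _, counts = md.histogram(field, bin_count=bins)
        sigma = np.sqrt(n * 0.1 * 0.9)
        assert np.all(np.abs(counts - n / bins) < 5 * sigma)

    def test_rightmost_bin_closed(self):
        _, counts = md.histogram(md.DistanceField([0.0, 0.5, 1.0], "C2C"), bin_count=2)
        assert counts.tolist() == [1, 2]


class TestHeatmapColors:
    def test_zero_field_all_cold_blue(self):
        colors = md.heatmap_colors(md.DistanceField([0.0, 0.0, 0.0], "C2C"),
                                   saturation_max=1.0)
        np.testing.assert_array_equal(colors, [[0, 0, 255]] * 3)

    def test_saturation_max_is_warm_red(self):
        colors = md.heatmap_colors(md.DistanceField([5.0, 9.0], "C2C"),
                                   saturation_max=5.0)
        np.testing.assert_array_equal(colors[0], [255, 0, 0])
        np.testing.assert_array_equal(colors[1], [255, 0, 0])  # clamped above max

    def test_monotone_cold_to_warm(self, rng):
        d = np.sort(rng.random(100))
        colors = md.heatmap_colors(md.DistanceField(d, "C2C"), saturation_max=1.0)
        red, blue = colors[:, 0].astype(int), colors[:, 2].astype(int)
        assert np.all(np.diff(red) >= 0)
        assert np.all(np.diff(blue) <= 0)


class TestCompare:
    def test_identical_meshes_zero_mean(self, claw):
        result = md.compare(claw, claw, mode="C2M", icp=True)
        assert result.summary.mean < 1e-9
        assert result.icp_result is not None

    def test_icp_never_worse_than_landmark_init(self, claw, claw_params,
                                                landmark_indices):
        moved, _ = md.plant_transform(claw, 1.4, (0.2, -0.1, 0.15), (4, 1, -2))
        lms = md.make_landmark_pair(moved, claw, landmark_indices)
        on = md.compare(moved, claw, mode="C2C", icp=True, landmarks=lms)
        off = md.compare(moved, claw, mode="C2C", icp=False, landmarks=lms)
        # noiseless planted pair: both land at numerical zero, ICP never worse
        assert on.summary.mean <= off.summary.mean + 1e-12
        assert on.pre_icp_summary is not None
        assert off.icp_result is None

    def test_degraded_target_field_size_tracks_surviving_vertices(
        self, claw, claw_params
    ):
        degraded, report = md.degrade(
            claw, md.DegradationSpec(noise_sd=0.0), claw_params
        )
        result = md.compare(degraded, claw, mode="C2M", icp=False)
        assert result.field.n == report.kept == degraded.n_vertices

    def test_invalid_mode_rejected(self, claw):
        with pytest.raises(md.ValidationError):
            md.compare(claw, claw, mode="C2X")
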
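"""Landmark similarity fit, scaled ICP, iteration sweeps, transform algebra."""
import inspect

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import morphodist as md
from morphodist.errors import DegenerateGeometryError


def random_similarity(rng, max_angle=np.pi):
    s = rng.uniform(0.5, 2.0)
    R = Rotation.from_rotvec(
        rng.uniform(-1, 1, 3) * max_angle / np.sqrt(3)
    ).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return md.SimilarityTransform(s, R, t)


class TestLandmarkSimilarity:
    def test_identity_pair(self, rng):
        pts = rng.normal(size=(5, 3))
        T = md.landmark_similarity(pts, pts)
        assert abs(T.scale - 1) < 1e-12
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.translation, 0, atol=1e-12)

    def test_pure_scaling_about_origin(self, rng):
        pts = rng.normal(size=(4, 3))
        T = md.landmark_similarity(pts, 2.0 * pts)
        assert abs(T.scale - 2.0) < 1e-10
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(T.translation, 0, atol=1e-9)

    def test_recovers_planted_similarity(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(6, 3))
            planted = random_similarity(rng)
            T = md.landmark_similarity(pts, planted.apply(pts))
            assert abs(T.scale - planted.scale) < 1e-8
            np.testing.assert_allclose(T.rotation, planted.rotation, atol=1e-8)
            resid = T.apply(pts) - planted.apply(pts)
            assert np.sqrt((resid**2).sum(axis=1).mean()) < 1e-10

    def test_rigid_mode_scale_exactly_one(self, rng):
        pts = rng.normal(size=(5, 3))
        T = md.landmark_similarity(pts, 3.0 * pts + 1.0, with_scale=False)
        assert T.scale == 1.0

    def test_matches_numeric_optimiser(self, rng):
        """Closed form must match an exhaustive numeric optimiser on noisy pairs."""

        def objective(theta, x, y, with_scale):
            s = np.exp(theta[0]) if with_scale else 1.0
            R = Rotation.from_rotvec(theta[1:4]).as_matrix()
            t = theta[4:7]
            return ((s * x @ R.T + t - y) ** 2).sum()

        for _ in range(5):
            x = rng.normal(size=(rng.integers(4, 7), 3))
            y = random_similarity(rng).apply(x) + 0.05 * rng.normal(size=x.shape)
            T = md.landmark_similarity(x, y)
            ours = ((T.apply(x) - y) ** 2).sum()
            best = min(
                minimize(
                    objective, np.concatenate([[0.0], rv, [0, 0, 0]]),
                    args=(x, y, True), method="Nelder-Mead",
                    options={"maxiter": 6000, "xatol": 1e-12, "fatol": 1e-14},
                ).fun
                for rv in ([0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5])
            )
            assert ours <= best + 1e-6

    def test_matches_trimesh_procrustes(self, rng):
        """Independent library cross-check of the scaled least-squares fit."""
        from trimesh.registration import procrustes

        x = rng.normal(size=(8, 3))
        y = random_similarity(rng).apply(x) + 0.02 * rng.normal(size=x.shape)
        T = md.landmark_similarity(x, y)
        _, transformed, cost = procrustes(x, y, reflection=False)
        ours = ((T.apply(x) - y) ** 2).mean()
        assert ours <= cost + 1e-9

    def test_too_few_pairs_rejected(self):
        with pytest.raises(md.ValidationError):
            md.landmark_similarity(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_configuration_rejected(self):
        line = np.outer(np.arange(4, dtype=float), [1.0, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            md.landmark_similarity(line, line + 1.0)


class TestIcpAlign:
    def test_exact_copy_converges_immediately(self, claw):
        cloud = md.mesh_to_cloud(claw)
        res = md.icp_align(cloud, cloud)
        assert res.iterations_run <= 2
        assert res.final_rms < 1e-10
        assert abs(res.transform.scale - 1) < 1e-9
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-9)

    def test_recovers_planted_similarity_from_landmark_init(self, claw, claw_params,
                                                            landmark_indices):
        moved, gt = md.plant_transform(claw, 0.8, (0.17, 0.0, 0.05), (2.0, -1.0, 0.5))
        lm_t, lm_r = md.make_landmark_pair(moved, claw, landmark_indices)
        init = md.landmark_similarity(lm_t, lm_r)
        res = md.icp_align(
            md.mesh_to_cloud(moved), md.mesh_to_cloud(claw), initial=init
        )
        assert res.final_rms < 1e-6
        assert abs(res.transform.scale - gt.scale) < 1e-4
        np.testing.assert_allclose(res.transform.rotation, gt.rotation, atol=1e-4)

    def test_default_budget_is_twenty(self):
        sig = inspect.signature(md.icp_align)
        assert sig.parameters["max_iterations"].default == 20

    def test_rms_history_non_increasing(self, rng):
        """The full-correspondence ICP objective can never increase."""
        for _ in range(10):
            ref = rng.normal(size=(120, 3)) * 5
            src = random_similarity(rng, max_angle=0.6).apply(
                ref[rng.choice(120, 90, replace=False)]
            )
            res = md.icp_align(md.PointCloud(src), md.PointCloud(ref))
            assert np.all(np.diff(res.rms_history) <= 1e-9)

    def test_invariant_under_common_rigid_motion(self, claw, rng):
        src = md.PointCloud(claw.vertices[::2] + rng.normal(0, 0.01, (claw.n_vertices // 2, 3)))
        ref = md.mesh_to_cloud(claw)
        base = md.icp_align(src, ref).final_rms
        motion = md.SimilarityTransform(
            1.0, Rotation.from_euler("xyz", [0.3, -0.2, 0.5]).as_matrix(), [4, 5, -6]
        )
        moved = md.icp_align(
            md.apply_transform(src, motion), md.apply_transform(ref, motion)
        ).final_rms
        assert abs(base - moved) < 1e-8

    def test_empty_source_rejected(self, claw):
        with pytest.raises(md.ValidationError):
            md.icp_align(np.zeros((0, 3)), md.mesh_to_cloud(claw))


class TestIterationSweep:
    def test_default_budgets_and_monotonicity(self, claw, claw_params, landmark_indices):
        moved, _ = md.plant_transform(claw, 1.2, (0.1, 0.05, -0.2), (1, 2, 3))
        lm_t, lm_r = md.make_landmark_pair(moved, claw, landmark_indices)
        init = md.landmark_similarity(lm_t, lm_r)
        sweep = md.iteration_sweep(
            md.mesh_to_cloud(moved), md.mesh_to_cloud(claw), initial=init
        )
        assert list(sweep.budgets) == list(range(5, 101, 5))
        assert len(sweep.budgets) == 20
        assert np.all(np.diff(sweep.rms) <= 1e-9)
        # a noiseless pair plateaus well before the budget ceiling
        assert sweep.plateau_budget is not None and sweep.plateau_budget < 100
        assert sweep.rms[-1] < 1e-6


class TestApplyTransform:
    def test_identity_is_noop(self, claw):
        out = md.apply_transform(claw, md.SimilarityTransform.identity())
        np.testing.assert_array_equal(out.vertices, claw.vertices)
        np.testing.assert_array_equal(out.faces, claw.faces)

    def test_composition_associates(self, rng):
        pts = rng.normal(size=(30, 3))
        T1, T2 = random_similarity(rng), random_similarity(rng)
        chained = md.apply_transform(md.apply_transform(pts, T1), T2)
        composed = md.apply_transform(pts, T2.compose(T1))
        np.testing.assert_allclose(chained, composed, atol=1e-10)

    def test_inverse_round_trip(self, rng):
        pts = rng.normal(size=(30, 3))
        T = random_similarity(rng)
        back = md.apply_transform(md.apply_transform(pts, T), T.inverse())
        np.testing.assert_allclose(back, pts, atol=1e-10)

    def test_reflection_rejected(self):
        with pytest.raises(md.ValidationError):
            md.SimilarityTransform(1.0, np.diag([1.0, 1.0, -1.0]), np.zeros(3))
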
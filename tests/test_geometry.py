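import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import spinereg as sr
from spinereg.geometry import invert_pose, transform_geometry

from conftest import random_pose


class TestRigidPose:
    def test_identity_and_translation(self):
        assert np.allclose(sr.apply_pose(sr.RigidPose.identity(), [[1, 2, 3]]), [[1, 2, 3]])
        p = sr.RigidPose.from_params([1, 2, 2, 0, 0, 0])
        assert np.allclose(sr.apply_pose(p, [0, 0, 0]), [1, 2, 2])

    def test_analytic_rotation(self):
        p = sr.RigidPose.from_params([0, 0, 0, 0, 0, 90])
        assert np.allclose(sr.apply_pose(p, [10, 0, 0]), [0, 10, 0], atol=1e-12)

    def test_rotation_matrix_proper(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            R = random_pose(rng).matrix
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.isclose(np.linalg.det(R), 1.0)

    def test_compose_equals_double_application(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            c = rng.uniform(-10, 10, 3)
            p = random_pose(rng, center=c)
            q = random_pose(rng, center=c)
            x = rng.uniform(-50, 50, (10, 3))
            direct = sr.apply_pose(p, sr.apply_pose(q, x))
            composed = sr.apply_pose(sr.compose_pose(p, q), x)
            assert np.allclose(direct, composed, atol=1e-9)

    def test_compose_with_inverse_is_identity(self):
        rng = np.random.default_rng(2)
        p = random_pose(rng)
        ident = sr.compose_pose(p, invert_pose(p))
        assert np.allclose(ident.params, 0.0, atol=1e-9)

    def test_mismatched_centers_rejected(self):
        a = sr.RigidPose.identity((0, 0, 0))
        b = sr.RigidPose.identity((1, 0, 0))
        with pytest.raises(ValueError, match="rotation center"):
            sr.compose_pose(a, b)

    def test_recenter_is_equivalent(self):
        rng = np.random.default_rng(3)
        p = random_pose(rng)
        q = p.recenter(rng.uniform(-30, 30, 3))
        x = rng.uniform(-50, 50, (5, 3))
        assert np.allclose(sr.apply_pose(p, x), sr.apply_pose(q, x), atol=1e-9)

    def test_rigidity_preserves_distances(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            p = random_pose(rng)
            x = rng.uniform(-100, 100, (8, 3))
            y = sr.apply_pose(p, x)
            dx = np.linalg.norm(x[:, None] - x[None, :], axis=2)
            dy = np.linalg.norm(y[:, None] - y[None, :], axis=2)
            assert np.allclose(dx, dy, atol=1e-9)


class TestUmeyama:
    def test_identity_for_equal_sets(self):
        pts = np.random.default_rng(0).normal(size=(6, 3)) * 30
        T, rms = sr.umeyama_align(pts, pts)
        assert rms < 1e-12
        assert np.allclose(T["rotation"], np.eye(3), atol=1e-12)
        assert np.allclose(T["translation"], 0, atol=1e-12)

    def test_recovers_constructed_transform(self):
        rng = np.random.default_rng(5)
        src = rng.normal(size=(6, 3)) * 20
        R = Rotation.from_euler("y", 30, degrees=True).as_matrix()
        dst = src @ R.T + np.array([5.0, -3.0, 2.0])
        T, rms = sr.umeyama_align(src, dst)
        assert rms < 1e-9
        assert np.allclose(T["rotation"], R, atol=1e-9)
        assert np.allclose(T["translation"], [5, -3, 2], atol=1e-9)

    def test_exactness_over_random_cases(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = rng.integers(5, 21)
            src = rng.normal(size=(n, 3)) * 50
            R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
            t = rng.uniform(-100, 100, 3)
            dst = src @ R.T + t
            T, rms = sr.umeyama_align(src, dst)
            assert rms < 1e-9

    def test_collinear_degenerate(self):
        line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="degenerate"):
            sr.umeyama_align(line, line + 1.0)

    def test_scale_mode(self):
        rng = np.random.default_rng(7)
        src = rng.normal(size=(8, 3)) * 10
        dst = 2.5 * src + 1.0
        T, rms = sr.umeyama_align(src, dst, with_scale=True)
        assert np.isclose(T["scale"], 2.5)
        assert rms < 1e-9


class TestProjection:
    def test_principal_point_and_magnification(self):
        g = sr.carm_geometry(0, sdd=1000, sod=600, pixel_pitch=1.0, detector_shape=(256, 256))
        rc0 = sr.project_points(g, g.isocenter)
        assert np.allclose(rc0, [127.5, 127.5])
        rc = sr.project_points(g, g.isocenter + np.array([10.0, 0, 0]))
        # similar triangles: 10 mm at SOD 600 -> 16.667 mm at SDD 1000
        assert np.isclose((rc - rc0)[1], 10 * 1000 / 600, atol=1e-9)

    def test_point_behind_source_raises(self):
        g = sr.carm_geometry(0)
        behind = g.source - 10 * g.axis
        with pytest.raises(ValueError, match="behind the source"):
            sr.project_points(g, behind)

    def test_projection_consistency_under_pose(self):
        rng = np.random.default_rng(8)
        g = sr.carm_geometry(25)
        for _ in range(10):
            t = random_pose(rng, t_scale=20, r_scale=20, center=np.zeros(3))
            x = rng.uniform(-40, 40, (6, 3))
            a = sr.project_points(g, sr.apply_pose(t, x))
            b = sr.project_points(transform_geometry(g, invert_pose(t)), x)
            assert np.allclose(a, b, atol=1e-6)

    def test_geometry_invariants_enforced(self):
        g = sr.carm_geometry(30)
        assert np.isclose(g.row_dir @ g.col_dir, 0, atol=1e-12)
        assert np.isclose(g.row_dir @ g.axis, 0, atol=1e-12)
        with pytest.raises(ValueError, match="SDD > SOD"):
            sr.carm_geometry(0, sdd=500, sod=600)


class TestRelativeAngulation:
    @pytest.mark.parametrize(
        "a1,a2,rad", [(-20.0, 20.0, 40.0), (0.0, 0.0, 0.0), (-45.0, 45.0, 90.0)]
    )
    def test_opposed_pairs(self, a1, a2, rad):
        rel = sr.relative_angulation(sr.carm_geometry(a1), sr.carm_geometry(a2))
        assert np.isclose(rel.rad_deg, rad, atol=1e-9)

    def test_rad_symmetric_and_inverse_invariant(self):
        g1, g2 = sr.carm_geometry(-28), sr.carm_geometry(32)
        r12 = sr.relative_angulation(g1, g2)
        r21 = sr.relative_angulation(g2, g1)
        assert np.isclose(r12.rad_deg, r21.rad_deg)
        assert np.isclose(r12.rad_deg, r12.inverse().rad_deg)
        assert 0.0 <= r12.rad_deg <= 180.0

    def test_relative_pose_maps_geometry(self):
        g1, g2 = sr.carm_geometry(-45), sr.carm_geometry(45)
        rel = sr.relative_angulation(g1, g2)
        moved = rel.apply_to_geometry(g1)
        assert np.allclose(moved.source, g2.source, atol=1e-9)
        assert np.allclose(moved.row_dir, g2.row_dir, atol=1e-12)
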
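import numpy as np
import pytest
from skimage.feature import peak_local_max

import spinereg as sr
from spinereg.projector import render_markers, simulate_fluoro


def _geometry(shape=(128, 128)):
    return sr.carm_geometry(0, sdd=1000, sod=600, pixel_pitch=1.0, detector_shape=shape)


class TestForwardProject:
    def test_zero_volume_zero_drr(self):
        vol = sr.VolumeImage(np.zeros((16, 16, 16)), np.ones(3), -7.5 * np.ones(3))
        drr = sr.forward_project(vol, _geometry((32, 32)))
        assert np.all(drr.values == 0)

    def test_sphere_chord_length_oracle(self, sphere_volume):
        # central ray chord through a homogeneous sphere: 2 * r * mu = 0.8
        drr = sr.forward_project(sphere_volume, _geometry(), step=0.25)
        central = drr.values[63:65, 63:65].mean()
        assert abs(central - 0.8) / 0.8 < 0.01

    def test_step_halving_converged(self, sphere_volume):
        g = _geometry()
        a = sr.forward_project(sphere_volume, g, step=0.5).values[64, 64]
        b = sr.forward_project(sphere_volume, g, step=0.25).values[64, 64]
        assert abs(a - b) / b < 0.005

    def test_linearity(self, sphere_volume):
        g = _geometry((64, 64))
        v2 = sr.VolumeImage(2 * sphere_volume.values, sphere_volume.spacing, sphere_volume.origin)
        d1 = sr.forward_project(sphere_volume, g, step=1.0).values
        d2 = sr.forward_project(v2, g, step=1.0).values
        assert np.allclose(d2, 2 * d1, atol=1e-6)

    def test_mask_additivity(self, phantom):
        volume, models = phantom
        g = sr.carm_geometry(20, detector_shape=(128, 128), pixel_pitch=2.0)
        union = np.zeros(volume.shape, dtype=bool)
        parts = np.zeros(g.detector_shape)
        for m in models:
            union |= m.mask
            parts += sr.forward_project(volume, g, mask=m.mask, step=1.0).values
        bg = sr.VolumeImage(volume.values * (~union), volume.spacing, volume.origin)
        parts += sr.forward_project(bg, g, step=1.0).values
        full = sr.forward_project(volume, g, step=1.0).values
        assert np.allclose(parts, full, atol=1e-6)

    def test_translated_landmark_follows_projection(self, phantom):
        volume, models = phantom
        g = sr.carm_geometry(15, detector_shape=(256, 256))
        m = models[2]
        pose = sr.RigidPose.from_params([3.0, -2.0, 1.5, 0, 0, 0], center=m.body_center)
        drr = sr.forward_project(volume, g, pose=pose, mask=m.body_mask, step=0.5)
        rc = sr.project_points(g, sr.apply_pose(pose, m.body_center))
        # centroid of the projected body lands on the projected landmark
        w = drr.values
        rr, cc = np.mgrid[0 : w.shape[0], 0 : w.shape[1]]
        com = np.array([(w * rr).sum(), (w * cc).sum()]) / w.sum()
        assert np.linalg.norm(com - rc) < 0.5

    def test_source_inside_volume_rejected(self):
        g = sr.carm_geometry(0, sdd=1000, sod=100.0)
        big = sr.VolumeImage(
            np.ones((16, 16, 16)), 20 * np.ones(3), np.array([-150.0, -150.0, -150.0])
        )
        with pytest.raises(ValueError, match="degenerate"):
            sr.forward_project(big, g)

    def test_roi_matches_full_computation(self, sphere_volume):
        g = _geometry((64, 64))
        roi = (slice(20, 40), slice(25, 45))
        full = sr.forward_project(sphere_volume, g, step=1.0).values
        part = sr.forward_project(sphere_volume, g, step=1.0, roi=roi).values
        assert np.allclose(part[roi], full[roi], atol=1e-12)
        part[roi] = 0
        assert np.all(part == 0)


class TestRenderMarkers:
    def test_peaks_at_projected_centers(self):
        mk = sr.place_markers(count=7, seed=1)
        g = sr.carm_geometry(30)
        img = render_markers(g, mk).values
        rc = sr.project_points(g, mk.centers)
        for r, c in rc:
            ri, ci = int(round(r)), int(round(c))
            w = img[ri - 3 : ri + 4, ci - 3 : ci + 4]
            pk = np.unravel_index(np.argmax(w), w.shape)
            assert np.linalg.norm([ri - 3 + pk[0] - r, ci - 3 + pk[1] - c]) <= 0.71

    def test_zero_outside_chords(self):
        centers = np.array(
            [[0.0, 0.0, 60.0], [70.0, 70.0, 60.0], [-70.0, 70.0, 60.0], [70.0, -70.0, 60.0], [-70.0, -70.0, 60.0]]
        )
        mk = sr.MarkerModel(centers, radius=3.0)
        g = sr.carm_geometry(0)
        img = render_markers(g, mk).values
        rc = sr.project_points(g, centers[0])
        # a ray missing every sphere (d >= r) contributes nothing
        assert img[int(rc[0]) + 30, int(rc[1])] == 0.0
        # peak equals the full-diameter chord 2 * mu * r
        peak = 2 * mk.attenuation * mk.radius
        assert abs(img.max() - peak) / peak < 0.05

    def test_nine_markers_nine_maxima(self):
        mk = sr.place_markers(count=9, seed=5)
        g = sr.carm_geometry(-30)
        img = render_markers(g, mk).values
        peaks = peak_local_max(img, min_distance=5, threshold_abs=0.1 * img.max())
        assert len(peaks) == 9

    def test_marker_behind_source_rejected(self):
        g = sr.carm_geometry(0)
        behind = g.source - 10 * g.axis
        others = np.tile([0.0, 0.0, 60.0], (4, 1)) + np.arange(4)[:, None] * np.array([30.0, 0.0, 0.0])
        mk = sr.MarkerModel(np.vstack([behind, others]))
        with pytest.raises(ValueError, match="behind the source"):
            render_markers(g, mk)


class TestSimulateFluoro:
    def test_zero_noise_equals_composite(self, phantom):
        volume, models = phantom
        models = sr.perturb_spine(models, seed=2)
        mk = sr.place_markers(count=8, seed=3)
        g = sr.carm_geometry(-30)
        poses = [m.true_pose for m in models]
        clean = sr.NoiseConfig(gain=0, gaussian_sd=0, intensity_scale=1.0, intensity_offset=0.0)
        fl = simulate_fluoro(volume, models, mk, g, poses, clean, seed=0)
        union = np.zeros(volume.shape, dtype=bool)
        for m in models:
            union |= m.mask
        from spinereg.phantom import MU_TISSUE

        bg = sr.VolumeImage(
            np.where(union, np.float32(MU_TISSUE), volume.values), volume.spacing, volume.origin
        )
        expected = sr.forward_project(bg, g).values
        for m, p in zip(models, poses):
            expected += sr.forward_project(volume, g, pose=p, mask=m.mask).values
        expected += render_markers(g, mk).values
        assert np.allclose(fl.values, expected, atol=1e-12)

    def test_seeded_noise_reproducible(self, phantom):
        volume, models = phantom
        models = sr.perturb_spine(models, seed=2)
        g = sr.carm_geometry(20, detector_shape=(128, 128), pixel_pitch=2.0)
        poses = [m.true_pose for m in models]
        a = simulate_fluoro(volume, models, None, g, poses, sr.NoiseConfig(), seed=5)
        b = simulate_fluoro(volume, models, None, g, poses, sr.NoiseConfig(), seed=5)
        assert np.array_equal(a.values, b.values)

    def test_intensity_scale_recovered_downstream(self, phantom):
        volume, models = phantom
        models = sr.perturb_spine(models, seed=2)
        g = sr.carm_geometry(20, detector_shape=(128, 128), pixel_pitch=2.0)
        poses = [m.true_pose for m in models]
        base = sr.NoiseConfig(gain=0, gaussian_sd=0, intensity_scale=1.0, intensity_offset=0.0)
        scaled = sr.NoiseConfig(gain=0, gaussian_sd=0, intensity_scale=2.0, intensity_offset=0.3)
        f1 = simulate_fluoro(volume, models, None, g, poses, base, seed=0)
        f2 = simulate_fluoro(volume, models, None, g, poses, scaled, seed=0)
        from spinereg.similarity import estimate_scale, gradient_images

        s, flag = estimate_scale(gradient_images(f2.values), gradient_images(f1.values))
        assert not flag
        assert np.isclose(s, 2.0, atol=1e-9)
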
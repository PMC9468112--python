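import numpy as np
import pytest

import spinereg as sr
from spinereg.phantom import resample_slice_thickness


class TestMakePhantom:
    def test_deterministic_and_labelled(self, phantom):
        volume, models = phantom
        v2, m2 = sr.make_phantom(seed=1)
        assert np.array_equal(volume.values, v2.values)
        assert [m.label for m in models] == ["T5", "T6", "T7", "T8", "T9"]
        assert len({m.label for m in models}) == 5

    def test_masks_pairwise_disjoint(self, phantom):
        _, models = phantom
        for i in range(len(models)):
            for j in range(i + 1, len(models)):
                assert not np.any(models[i].mask & models[j].mask)

    def test_landmarks_inside_mask_bbox(self, phantom):
        volume, models = phantom
        for m in models:
            lo, hi = m.mask_bbox_world(volume)
            for p in (m.body_center, m.left_pedicle):
                assert np.all(p >= lo - 1e-9) and np.all(p <= hi + 1e-9)

    def test_body_center_matches_body_mask_centroid(self, phantom):
        volume, models = phantom
        for m in models:
            idx = np.array(np.nonzero(m.body_mask), dtype=float)
            centroid = volume.index_to_world(idx.mean(axis=1))
            assert np.all(np.abs(centroid - m.body_center) <= volume.spacing)

    def test_volume_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            sr.make_phantom(n_vertebrae=12, shape=(32, 32, 32))

    def test_intensities_nonnegative_anisotropy_allowed(self, phantom):
        volume, _ = phantom
        assert volume.values.min() >= 0
        assert volume.spacing[1] < volume.spacing[0]  # 0.67 mm slices


class TestPerturbSpine:
    def test_zero_ranges_identity(self, phantom):
        _, models = phantom
        zero = sr.PerturbRanges(tx=0, ty=0, tz=0, wx=0, wy=0, wz=0)
        out = sr.perturb_spine(models, zero, seed=3)
        for m in out:
            assert np.allclose(m.true_pose.params, 0.0)

    def test_default_ranges_respected(self, phantom):
        _, models = phantom
        for seed in range(10):
            out = sr.perturb_spine(models, seed=seed)
            for m in out:
                q = m.true_pose.params
                assert abs(q[3]) <= 5.0  # rotation about x
                assert abs(q[2]) <= 2.0  # translation along z
                assert np.allclose(q[[0, 1, 4, 5]], 0.0)
                assert np.allclose(m.true_pose.center, m.body_center)

    def test_reproducible(self, phantom):
        _, models = phantom
        a = sr.perturb_spine(models, seed=9)
        b = sr.perturb_spine(models, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.true_pose.params, y.true_pose.params)


class TestPlaceMarkers:
    def test_counts_and_separation(self):
        m = sr.place_markers(count=9, seed=2)
        assert m.count == 9
        d = np.linalg.norm(m.centers[:, None] - m.centers[None, :], axis=2)
        d[np.diag_indices(9)] = np.inf
        assert d.min() > 2 * m.radius

    def test_minimum_five_markers(self):
        with pytest.raises(ValueError, match="5 skin markers"):
            sr.place_markers(count=4)

    def test_within_frame(self):
        for seed in range(5):
            m = sr.place_markers(count=8, frame=(150.0, 150.0), seed=seed)
            assert np.all(np.abs(m.centers[:, 0]) <= 75.0)
            assert np.all(np.abs(m.centers[:, 1]) <= 75.0)

    def test_convex_skin_relief(self):
        m = sr.place_markers(count=9, seed=4, skin_z=60.0, sagittal_drop=25.0)
        # lateral markers sit lower (smaller z) than midline ones
        lateral = np.abs(m.centers[:, 0]) > 50
        if lateral.any() and (~lateral).any():
            assert m.centers[lateral, 2].mean() < m.centers[~lateral, 2].mean()


class TestSliceThickness:
    def test_identity_resample(self, phantom):
        volume, _ = phantom
        out = resample_slice_thickness(volume, volume.spacing[1])
        assert np.allclose(out.values, volume.values, atol=1e-6)

    def test_slice_count_ratio(self, phantom):
        volume, _ = phantom
        out = resample_slice_thickness(volume, 5.0)
        expected = volume.shape[1] * volume.spacing[1] / 5.0
        assert abs(out.shape[1] - expected) <= 1
        assert out.spacing[1] == 5.0

    def test_invalid_thickness(self, phantom):
        volume, _ = phantom
        with pytest.raises(ValueError):
            resample_slice_thickness(volume, -1.0)
        with pytest.raises(ValueError, match=">= the original"):
            resample_slice_thickness(volume, 0.1)

    def test_world_coordinates_preserved(self, phantom):
        volume, _ = phantom
        out = resample_slice_thickness(volume, 2.0)
        # center of the stack stays put
        assert abs(out.center_mm[1] - volume.center_mm[1]) < 2.0


class TestMakeTestCase:
    @pytest.mark.parametrize("pair,rad", [((-45.0, 45.0), 90.0), ((-20.0, 20.0), 40.0)])
    def test_nominal_rad_recorded(self, pair, rad):
        cfg = sr.CaseConfig(angulation_pair=pair)
        tc = sr.make_test_case(cfg, seed=0)
        assert tc.rad_deg == rad
        assert abs(tc.realized_rad_deg - rad) <= 2 * cfg.angulation_jitter_deg + 1e-9

    def test_bit_reproducible(self):
        cfg = sr.CaseConfig()
        a = sr.make_test_case(cfg, seed=4)
        b = sr.make_test_case(cfg, seed=4)
        assert np.array_equal(a.fluoro1.values, b.fluoro1.values)
        assert np.array_equal(a.fluoro2.values, b.fluoro2.values)
        assert np.array_equal(a.markers.centers, b.markers.centers)

    def test_marker_projections_hit_rendered_peaks(self, noise_free_case):
        # geometric self-consistency: projecting the true marker centers
        # lands on the intensity peaks of the synthetic images
        tc = noise_free_case
        for fl, g in [(tc.fluoro1, tc.geometry1), (tc.fluoro2, tc.geometry2)]:
            rc = sr.project_points(g, tc.markers.centers)
            img = fl.values
            for r, c in rc:
                ri, ci = int(round(r)), int(round(c))
                w = img[ri - 4 : ri + 5, ci - 4 : ci + 5]
                pk = np.unravel_index(np.argmax(w), w.shape)
                peak_rc = np.array([ri - 4 + pk[0], ci - 4 + pk[1]])
                assert np.linalg.norm(peak_rc - [r, c]) <= 0.71  # within half a pixel

    def test_all_vertebrae_captured_by_default(self, default_case):
        tc = default_case
        from spinereg.register import check_capture

        for v in tc.vertebrae:
            assert check_capture(v, v.true_pose, tc.volume, tc.geometry1, tc.geometry2)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="5 skin markers"):
            sr.CaseConfig(marker_count=4)
        with pytest.raises(ValueError, match="45"):
            sr.CaseConfig(angulation_pair=(-50.0, 50.0))
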
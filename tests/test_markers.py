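import numpy as np
import pytest

import spinereg as sr
from spinereg.markers import (
    Detection2D,
    detect_markers_2d,
    estimate_relative_pose,
    match_markers,
)
from spinereg.projector import render_markers, simulate_fluoro


@pytest.fixture(scope="module")
def marker_scene():
    """Markers rendered over a mild soft-tissue background in two views."""
    cfg = sr.CaseConfig(marker_count=9, angulation_pair=(-45.0, 45.0), angulation_jitter_deg=0.0)
    mk = sr.place_markers(count=9, seed=3)
    g1 = cfg.geometry(-45.0, (0, 0, 0))
    g2 = cfg.geometry(45.0, (0, 0, 0))
    return cfg, mk, g1, g2


def _ideal_detections(g, mk, noise=0.0, rng=None):
    rc = sr.project_points(g, mk.centers)
    if noise > 0:
        rc = rc + rng.normal(0, noise, rc.shape)
    n = rc.shape[0]
    return Detection2D(rc, np.ones(n), np.full(n, 4.0))


class TestDetection:
    def test_blank_image_empty(self):
        d = detect_markers_2d(np.zeros((64, 64)))
        assert d.count == 0

    @pytest.mark.parametrize("count", [7, 9])
    def test_rendered_markers_found_subpixel(self, count):
        mk = sr.place_markers(count=count, seed=11)
        g = sr.carm_geometry(-30)
        img = render_markers(g, mk).values + 0.2  # flat background
        d = detect_markers_2d(img, (2.5, 7.0))
        assert d.count == count
        rc_true = sr.project_points(g, mk.centers)
        for c in d.centroids:
            assert np.min(np.linalg.norm(rc_true - c, axis=1)) < 0.5

    def test_detections_sorted_and_separated(self):
        mk = sr.place_markers(count=8, seed=2)
        g = sr.carm_geometry(20)
        d = detect_markers_2d(render_markers(g, mk).values, (2.5, 7.0))
        assert np.all(np.diff(d.responses) <= 1e-12)
        dd = np.linalg.norm(d.centroids[:, None] - d.centroids[None, :], axis=2)
        dd[np.diag_indices(d.count)] = np.inf
        assert dd.min() > 2 * d.radii_px.min()

    def test_detection_on_full_simulated_view(self, default_case):
        tc = default_case
        d = detect_markers_2d(tc.fluoro1, (2.5, 7.0), max_detections=tc.markers.count)
        rc_true = sr.project_points(tc.geometry1, tc.markers.centers)
        assert d.count == tc.markers.count
        errs = [np.min(np.linalg.norm(rc_true - c, axis=1)) for c in d.centroids]
        assert np.median(errs) < 0.5


class TestMatching:
    def test_true_bijection_recovered(self, marker_scene):
        cfg, mk, g1, g2 = marker_scene
        d1, d2 = _ideal_detections(g1, mk), _ideal_detections(g2, mk)
        pairs = match_markers(d1, d2, g1, g2)
        assert pairs == [(i, i) for i in range(9)]

    def test_shuffled_detections_same_correspondence(self, marker_scene):
        cfg, mk, g1, g2 = marker_scene
        d1, d2 = _ideal_detections(g1, mk), _ideal_detections(g2, mk)
        rng = np.random.default_rng(0)
        perm = rng.permutation(9)
        d2s = Detection2D(d2.centroids[perm], d2.responses[perm], d2.radii_px[perm])
        pairs = match_markers(d1, d2s, g1, g2)
        recovered = {(i, int(perm[j])) for i, j in pairs}
        assert recovered == {(i, i) for i in range(9)}

    def test_insufficient_detections_rejected(self, marker_scene):
        cfg, mk, g1, g2 = marker_scene
        d1 = _ideal_detections(g1, mk)
        d4 = Detection2D(d1.centroids[:4], d1.responses[:4], d1.radii_px[:4])
        with pytest.raises(ValueError, match="5 detected markers"):
            match_markers(d4, d1, g1, g2)


class TestRelativePose:
    def test_noise_free_recovery(self, marker_scene):
        cfg, mk, g1, _ = marker_scene
        g2_true = cfg.geometry(46.5, (0, 0, 0))
        g2_nom = cfg.geometry(45.0, (0, 0, 0))
        d1 = _ideal_detections(g1, mk)
        d2 = _ideal_detections(g2_true, mk)
        pairs = [(i, i) for i in range(9)]
        rel = estimate_relative_pose(d1, d2, pairs, g1, g2_nom, model_points=mk.centers)
        true_rad = sr.relative_angulation(g1, g2_true).rad_deg
        assert abs(rel.rad_deg - true_rad) < 0.2

    def test_identical_views_identity(self, marker_scene):
        cfg, mk, g1, _ = marker_scene
        d1 = _ideal_detections(g1, mk)
        rel = estimate_relative_pose(d1, d1, [(i, i) for i in range(9)], g1, g1, model_points=mk.centers)
        assert rel.rad_deg < 1e-9
        assert np.allclose(rel.translation, 0.0, atol=1e-9)

    def test_too_few_matches_rejected(self, marker_scene):
        cfg, mk, g1, g2 = marker_scene
        d1 = _ideal_detections(g1, mk)
        with pytest.raises(ValueError, match="5 matched"):
            estimate_relative_pose(d1, d1, [(i, i) for i in range(4)], g1, g2)

    def test_collinear_markers_degenerate(self, marker_scene):
        cfg, mk, g1, _ = marker_scene
        g2 = cfg.geometry(45.0, (0, 0, 0))
        line = np.outer(np.linspace(-60, 60, 6), [0.0, 1.0, 0.0]) + [0.0, 0.0, 55.0]
        lm = sr.MarkerModel(line)
        d1 = _ideal_detections(g1, lm)
        d2 = _ideal_detections(g2, lm)
        with pytest.raises(ValueError, match="collinear|degenerate"):
            estimate_relative_pose(d1, d2, [(i, i) for i in range(6)], g1, g2, model_points=line)

    def test_more_markers_never_hurt_noise_free(self):
        cfg = sr.CaseConfig(angulation_pair=(-45.0, 45.0))
        g1 = cfg.geometry(-45.0, (0, 0, 0))
        g2_true = cfg.geometry(46.0, (0, 0, 0))
        g2_nom = cfg.geometry(45.0, (0, 0, 0))
        true_rad = sr.relative_angulation(g1, g2_true).rad_deg
        medians = []
        for count in (5, 9):
            errs = []
            for seed in range(20):
                mk = sr.place_markers(count=count, seed=seed)
                d1, d2 = _ideal_detections(g1, mk), _ideal_detections(g2_true, mk)
                rel = estimate_relative_pose(
                    d1, d2, [(i, i) for i in range(count)], g1, g2_nom, model_points=mk.centers
                )
                errs.append(abs(rel.rad_deg - true_rad))
            medians.append(np.median(errs))
        assert medians[1] <= medians[0] + 1e-6

    def test_self_consistency_of_refined_geometry(self, marker_scene):
        cfg, mk, g1, _ = marker_scene
        g2_true = cfg.geometry(46.5, (0, 0, 0))
        g2_nom = cfg.geometry(45.0, (0, 0, 0))
        rng = np.random.default_rng(1)
        noise = 0.3
        d1 = _ideal_detections(g1, mk, noise, rng)
        d2 = _ideal_detections(g2_true, mk, noise, rng)
        rel, info = estimate_relative_pose(
            d1, d2, [(i, i) for i in range(9)], g1, g2_nom, model_points=mk.centers, return_info=True
        )
        g2_ref = info["refined_geometry2"]
        X = info["model_points_mm"]
        r1 = sr.project_points(g1, X) - d1.centroids
        r2 = sr.project_points(g2_ref, X) - d2.centroids
        rms = np.sqrt(np.mean(np.concatenate([r1, r2]) ** 2))
        assert rms < 2 * noise
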
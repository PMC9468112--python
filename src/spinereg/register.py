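"""Two-stage 3D/2D registration driver.

Stage 1 ("rough"): using one view only, a single shared pose of the
centered vertebra and its cranial neighbour is optimized at half detector
resolution — this shrinks the search space for stage 2.  Stage 2: each
vertebra is matched separately to both views (whose relative pose is fixed
— estimated from the skin markers or taken from ground truth), maximizing
the unweighted sum of the gradient-difference similarities of the two
views over the vertebra's 6-DOF pose, multi-resolution (half then full).

All optimization is CMA-ES; every stage draws its randomness from an
explicit seed, so a whole case registration is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.measure import block_reduce

from .geometry import RigidPose, ProjectionGeometry, RelativePose, apply_pose, project_points
from .phantom import VolumeImage, VertebraModel, TestCase
from .projector import FluoroImage, forward_project
from .similarity import SimilarityConfig, gradient_difference_similarity
from .optimize import cma_es_minimize
from .markers import detect_markers_2d, match_markers, estimate_relative_pose

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "check_capture",
    "stage1_coarse",
    "stage2_per_vertebra",
    "register_case",
]


@dataclass
class RegistrationConfig:
    """Hyperparameters of the two-stage search.

    Steps/budgets are deliberately modest: the similarity is evaluated only
    over the dilated projected bounding box of the vertebra being matched,
    so a stage-2 run costs a few hundred small DRRs.
    """

    sigma0_mm_deg: tuple = (2.0, 2.0, 2.0, 2.0, 2.0, 2.0)
    search_bound_mm: float = 10.0
    search_bound_deg: float = 10.0
    # a single view cannot observe translation along its own ray (only
    # magnification changes), so the stage-1 search is clamped tightly in
    # that direction to keep the coarse pose from drifting in depth
    stage1_depth_bound_mm: float = 2.0
    stage1_evals: int = 400
    stage2_evals_half: int = 300
    stage2_evals_full: int = 300
    ftol_rel: float = 1e-3
    roi_dilation_px: int = 5
    use_estimated_relative_pose: bool = True
    exclude_sacral: bool = True
    marker_radius_px_range: tuple = (2.5, 7.0)
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)


@dataclass
class RegistrationResult:
    """Outcome for one vertebra.  ``captured`` False means the vertebra did
    not project fully onto both detectors and no pose is reported;
    ``converged`` False excludes the result from accuracy summaries."""

    label: str
    pose: Optional[RigidPose]
    similarity: float = np.nan
    similarity_per_view: tuple = (np.nan, np.nan)
    evaluations: int = 0
    converged: bool = False
    captured: bool = True
    note: str = ""


def check_capture(
    vertebra: VertebraModel,
    pose: RigidPose,
    volume: VolumeImage,
    g1: ProjectionGeometry,
    g2: Optional[ProjectionGeometry] = None,
    margin_px: float = 0.0,
) -> bool:
    """True iff the vertebra's posed mask bounding box projects fully inside
    every given detector."""
    bbox = vertebra.mask_bbox_world(volume)
    corners = np.array(
        [[bbox[i, 0], bbox[j, 1], bbox[k, 2]] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    )
    moved = apply_pose(pose, corners)
    for g in (g1, g2):
        if g is None:
            continue
        try:
            rc = project_points(g, moved)
        except ValueError:
            return False
        rows, cols = g.detector_shape
        if (
            rc[:, 0].min() < -0.5 + margin_px
            or rc[:, 1].min() < -0.5 + margin_px
            or rc[:, 0].max() > rows - 0.5 - margin_px
            or rc[:, 1].max() > cols - 0.5 - margin_px
        ):
            return False
    return True


def _downsample_view(fluoro: FluoroImage, g: ProjectionGeometry, factor: int):
    if factor == 1:
        return np.asarray(fluoro.values, dtype=float), g
    gd = g.downsample(factor)
    rows, cols = gd.detector_shape
    img = block_reduce(
        np.asarray(fluoro.values, dtype=float)[: rows * factor, : cols * factor],
        (factor, factor),
        np.mean,
    )
    return img, gd


def _roi_bounds(g, volume, masks, pose, margin_px: int):
    """Rectangular detector window covering the projected bounding boxes of
    ``masks`` under ``pose``, grown by ``margin_px``."""
    pts = []
    for mask in masks:
        idx = np.nonzero(mask)
        lo = np.array([i.min() for i in idx])
        hi = np.array([i.max() for i in idx])
        for i in (lo[0], hi[0]):
            for j in (lo[1], hi[1]):
                for k in (lo[2], hi[2]):
                    pts.append(volume.index_to_world((i, j, k)))
    rc = project_points(g, apply_pose(pose, np.array(pts)))
    rows, cols = g.detector_shape
    r0 = int(np.clip(np.floor(rc[:, 0].min()) - margin_px, 0, rows - 2))
    r1 = int(np.clip(np.ceil(rc[:, 0].max()) + margin_px, r0 + 1, rows - 1))
    c0 = int(np.clip(np.floor(rc[:, 1].min()) - margin_px, 0, cols - 2))
    c1 = int(np.clip(np.ceil(rc[:, 1].max()) + margin_px, c0 + 1, cols - 1))
    return (slice(r0, r1 + 1), slice(c0, c1 + 1))


def _masked_similarity(volume, mask, pose, g, fl_img, roi, step, sim_cfg, keep=None):
    drr = forward_project(volume, g, pose=pose, mask=mask, step=step, roi=roi)
    if keep is not None:
        from dataclasses import replace as _rep

        sim_cfg = _rep(sim_cfg, roi=keep[roi])
    return gradient_difference_similarity(fl_img[roi], drr.values[roi], sim_cfg)


def _marker_keep_mask(det_shape, centroids, radii, factor: int = 1, grow: float = 1.8):
    """Boolean detector mask that is False inside (grown) marker footprints.

    Marker gradients cannot be explained by a vertebra DRR, so the
    similarity ignores those pixels.
    """
    rows, cols = det_shape
    keep = np.ones((rows, cols), dtype=bool)
    if centroids is None or len(centroids) == 0:
        return keep
    rr, cc = np.mgrid[0:rows, 0:cols]
    for (r0, c0), rad in zip(np.asarray(centroids) / factor, np.asarray(radii)):
        rex = (grow * rad) / factor + 1.0
        keep &= (rr - r0) ** 2 + (cc - c0) ** 2 > rex**2
    return keep


def _converged(trace) -> bool:
    # a contracted step size means the search settled into a basin even if
    # the evaluation budget (rather than the stagnation rule) ended the run
    if trace.stopped in ("stagnation", "sigma-collapse"):
        return True
    return bool(trace.sigma) and trace.sigma[-1] < 0.8


def stage1_coarse(
    volume: VolumeImage,
    vertebra_pair,
    fluoro1: FluoroImage,
    g1: ProjectionGeometry,
    cfg: RegistrationConfig = RegistrationConfig(),
    seed: int = 0,
    init_pose: Optional[RigidPose] = None,
    marker_px=None,
):
    """Single-view coarse registration of two adjacent vertebrae sharing one
    pose (about the volume center), at half detector resolution.

    ``marker_px`` is an optional ``(centroids, radii)`` pair of detected
    marker footprints to exclude from the similarity support.
    Returns ``(RigidPose, trace)``.
    """
    center = volume.center_mm
    if init_pose is None:
        init_pose = RigidPose.identity(center)
    else:
        init_pose = init_pose.recenter(center)
    masks = [v.mask for v in vertebra_pair]
    union = masks[0] | masks[1]
    for v in vertebra_pair:
        if not check_capture(v, init_pose.recenter(v.body_center), volume, g1):
            raise ValueError(f"vertebra {v.label} not captured in view 1")

    img, g = _downsample_view(fluoro1, g1, 2)
    step = float(np.min(volume.spacing))
    # ROI margin covers the translational search range at this magnification
    mag_px = cfg.search_bound_mm * g.sdd / g.sod / g.pixel_pitch
    roi = _roi_bounds(g, volume, [union], init_pose, int(np.ceil(mag_px)) + cfg.roi_dilation_px)
    keep = (
        _marker_keep_mask(g.detector_shape, marker_px[0], marker_px[1], factor=2)
        if marker_px is not None
        else None
    )

    # translation is searched in the camera basis (detector column, row,
    # viewing axis) so the unobservable depth direction can be bounded
    B = np.stack([g1.col_dir, g1.row_dir, g1.axis], axis=1)
    q0 = init_pose.params.copy()
    q0[:3] = B.T @ q0[:3]
    lb = q0 - np.array(
        [cfg.search_bound_mm, cfg.search_bound_mm, cfg.stage1_depth_bound_mm]
        + [cfg.search_bound_deg] * 3
    )
    ub = q0 + np.array(
        [cfg.search_bound_mm, cfg.search_bound_mm, cfg.stage1_depth_bound_mm]
        + [cfg.search_bound_deg] * 3
    )
    sigma = np.asarray(cfg.sigma0_mm_deg, dtype=float).copy()
    sigma[2] = min(sigma[2], 0.5 * cfg.stage1_depth_bound_mm)

    def _to_patient(qc):
        q = np.asarray(qc, dtype=float).copy()
        q[:3] = B @ q[:3]
        return q

    def objective(qc):
        pose = RigidPose.from_params(_to_patient(qc), center)
        return -_masked_similarity(volume, union, pose, g, img, roi, step, cfg.similarity, keep)

    best, trace = cma_es_minimize(
        objective,
        q0,
        sigma,
        bounds=(lb, ub),
        seed=seed,
        max_evals=cfg.stage1_evals,
        ftol_rel=cfg.ftol_rel,
    )
    return RigidPose.from_params(_to_patient(best), center), trace


def stage2_per_vertebra(
    volume: VolumeImage,
    vertebra: VertebraModel,
    fluoro1: FluoroImage,
    fluoro2: FluoroImage,
    g1: ProjectionGeometry,
    rel: RelativePose,
    init_pose: RigidPose,
    cfg: RegistrationConfig = RegistrationConfig(),
    seed: int = 0,
    marker_px1=None,
    marker_px2=None,
) -> RegistrationResult:
    """Register one vertebra to both views simultaneously.

    The view-2 geometry is view 1 composed with the (estimated or true)
    relative pose; the objective is the unweighted sum S1 + S2 of the
    gradient-difference similarities; CMA-ES runs at half then full
    resolution.
    """
    center = vertebra.body_center
    init_pose = init_pose.recenter(center)
    g2 = rel.apply_to_geometry(g1)
    if not check_capture(vertebra, init_pose, volume, g1, g2):
        return RegistrationResult(
            vertebra.label, None, captured=False, note="not fully captured on both views"
        )

    q = init_pose.params
    evals = 0
    traces = []
    rng = np.random.SeedSequence(seed).spawn(2)
    for level, (factor, budget, sig_scale) in enumerate(
        [(2, cfg.stage2_evals_half, 1.0), (1, cfg.stage2_evals_full, 0.3)]
    ):
        img1, gg1 = _downsample_view(fluoro1, g1, factor)
        img2, gg2 = _downsample_view(fluoro2, g2, factor)
        step = (1.0 if factor == 2 else 0.5) * float(np.min(volume.spacing))
        margin = cfg.roi_dilation_px + int(
            np.ceil(cfg.search_bound_mm * gg1.sdd / gg1.sod / gg1.pixel_pitch)
        )
        pose_now = RigidPose.from_params(q, center)
        roi1 = _roi_bounds(gg1, volume, [vertebra.mask], pose_now, margin)
        roi2 = _roi_bounds(gg2, volume, [vertebra.mask], pose_now, margin)
        keep1 = (
            _marker_keep_mask(gg1.detector_shape, marker_px1[0], marker_px1[1], factor=factor)
            if marker_px1 is not None
            else None
        )
        keep2 = (
            _marker_keep_mask(gg2.detector_shape, marker_px2[0], marker_px2[1], factor=factor)
            if marker_px2 is not None
            else None
        )
        lb = q - np.array([cfg.search_bound_mm] * 3 + [cfg.search_bound_deg] * 3)
        ub = q + np.array([cfg.search_bound_mm] * 3 + [cfg.search_bound_deg] * 3)

        def objective(qv):
            pose = RigidPose.from_params(qv, center)
            s1 = _masked_similarity(volume, vertebra.mask, pose, gg1, img1, roi1, step, cfg.similarity, keep1)
            s2 = _masked_similarity(volume, vertebra.mask, pose, gg2, img2, roi2, step, cfg.similarity, keep2)
            return -(s1 + s2)

        q, trace = cma_es_minimize(
            objective,
            q,
            sig_scale * np.asarray(cfg.sigma0_mm_deg),
            bounds=(lb, ub),
            seed=int(rng[level].generate_state(1)[0] % (2**31)),
            max_evals=budget,
            ftol_rel=cfg.ftol_rel,
        )
        evals += trace.evaluations
        traces.append(trace)

    pose = RigidPose.from_params(q, center)
    # final per-view similarity at full resolution
    img1, gg1 = _downsample_view(fluoro1, g1, 1)
    img2, gg2 = _downsample_view(fluoro2, g2, 1)
    step = 0.5 * float(np.min(volume.spacing))
    roi1 = _roi_bounds(gg1, volume, [vertebra.mask], pose, cfg.roi_dilation_px)
    roi2 = _roi_bounds(gg2, volume, [vertebra.mask], pose, cfg.roi_dilation_px)
    s1 = _masked_similarity(volume, vertebra.mask, pose, gg1, img1, roi1, step, cfg.similarity)
    s2 = _masked_similarity(volume, vertebra.mask, pose, gg2, img2, roi2, step, cfg.similarity)
    return RegistrationResult(
        label=vertebra.label,
        pose=pose,
        similarity=s1 + s2,
        similarity_per_view=(s1, s2),
        evaluations=evals,
        converged=all(_converged(t) for t in traces),
        captured=True,
    )


def register_case(
    tc: TestCase,
    cfg: RegistrationConfig = RegistrationConfig(),
    seed: int = 0,
):
    """Full pipeline on a test case: marker-based relative pose, stage-1
    coarse search on the centered pair, stage-2 per-vertebra registration
    of every captured (non-sacral) vertebra.

    Returns ``(results, info)`` where ``results`` is a list of
    :class:`RegistrationResult` (capture failures included, flagged, with
    no pose; sacral vertebrae omitted) and ``info`` records the relative
    pose actually used.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 + len(tc.vertebrae))]
    g1 = tc.geometry1

    info = {}
    if cfg.use_estimated_relative_pose:
        d1 = detect_markers_2d(
            tc.fluoro1, cfg.marker_radius_px_range, max_detections=tc.markers.count
        )
        d2 = detect_markers_2d(
            tc.fluoro2, cfg.marker_radius_px_range, max_detections=tc.markers.count
        )
        nominal_g2 = tc.config.geometry(tc.config.angulation_pair[1], isocenter=(0.0, 0.0, 0.0))
        pairs = match_markers(d1, d2, g1, nominal_g2)
        rel, mp_info = estimate_relative_pose(
            d1, d2, pairs, g1, nominal_g2, model_points=tc.markers.centers, return_info=True
        )
        info["marker_pose"] = mp_info
        marker_px1 = (d1.centroids, d1.radii_px)
        marker_px2 = (d2.centroids, d2.radii_px)
    else:
        rel = tc.true_relative_pose
        # ground-truth marker footprints for similarity exclusion
        marker_px1, marker_px2 = [], []
        for g, out in ((tc.geometry1, marker_px1), (tc.geometry2, marker_px2)):
            rc = project_points(g, tc.markers.centers)
            dist = np.linalg.norm(tc.markers.centers - g.source, axis=1)
            radii = tc.markers.radius * g.sdd / dist / g.pixel_pitch
            out.extend([rc, radii])
    info["relative_pose"] = rel
    info["rad_deg"] = rel.rad_deg

    labels = [v.label for v in tc.vertebrae]
    ic = len(tc.vertebrae) // 2
    i_cranial = max(ic - 1, 0)
    coarse, trace1 = stage1_coarse(
        tc.volume,
        (tc.vertebrae[i_cranial], tc.vertebrae[ic]),
        tc.fluoro1,
        g1,
        cfg,
        seed=seeds[0],
        marker_px=marker_px1,
    )
    info["stage1_pose"] = coarse
    info["stage1_converged"] = _converged(trace1)

    results = []
    for k, v in enumerate(tc.vertebrae):
        if cfg.exclude_sacral and v.label.startswith("S"):
            info.setdefault("excluded", []).append(v.label)
            continue
        res = stage2_per_vertebra(
            tc.volume,
            v,
            tc.fluoro1,
            tc.fluoro2,
            g1,
            rel,
            coarse,
            cfg,
            seed=seeds[2 + k],
            marker_px1=marker_px1,
            marker_px2=marker_px2,
        )
        results.append(res)
    return results, info
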
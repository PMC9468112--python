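"""Radiopaque skin-marker detection and two-view relative pose estimation.

The relative angulation (RAD) between the two fluoroscopic views is never
calibrated or tracked; it is recovered from the sphere markers themselves:
detect subpixel marker centroids in both images, match them by triangulation
consistency under the nominal (coarsely known) geometry, then alternate
between triangulating a 3D marker model and rigidly re-aligning the view-2
camera onto it with the Umeyama closed form.

With image correspondences alone the magnitude of the inter-view baseline is
a flat (unobservable) direction — rotations and the RAD are fully
observable.  The iteration therefore starts from the nominal geometry,
whose baseline scale it preserves, and only refines what the data
constrain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.feature import blob_log

from .geometry import ProjectionGeometry, RelativePose, relative_angulation, umeyama_align

__all__ = ["Detection2D", "detect_markers_2d", "match_markers", "estimate_relative_pose"]


@dataclass
class Detection2D:
    """Subpixel marker detections in one image, sorted by response."""

    centroids: np.ndarray  # (N, 2) pixel (row, col)
    responses: np.ndarray  # (N,)
    radii_px: np.ndarray  # (N,)

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        self.responses = np.asarray(self.responses, dtype=float).reshape(-1)
        self.radii_px = np.asarray(self.radii_px, dtype=float).reshape(-1)

    @property
    def count(self) -> int:
        return self.centroids.shape[0]


def _refine_centroid(img: np.ndarray, r0: float, c0: float, win: int) -> np.ndarray:
    """Subpixel centroid: intensity-weighted start, then a least-squares fit
    of the analytic sphere-chord profile ``b + a*sqrt(R^2 - d^2)`` (the
    radiograph of a homogeneous sphere on a locally flat background)."""
    rc = np.array([r0, c0], dtype=float)
    for _ in range(2):
        ri, ci = int(round(rc[0])), int(round(rc[1]))
        r_lo, r_hi = max(ri - win, 0), min(ri + win + 1, img.shape[0])
        c_lo, c_hi = max(ci - win, 0), min(ci + win + 1, img.shape[1])
        patch = img[r_lo:r_hi, c_lo:c_hi]
        border = np.concatenate([patch[0, :], patch[-1, :], patch[:, 0], patch[:, -1]])
        w = np.clip(patch - np.median(border), 0.0, None)
        tot = w.sum()
        if tot <= 0:
            return rc
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        rc = np.array([(w * rr).sum() / tot, (w * cc).sum() / tot])

    from scipy.optimize import least_squares as _lsq

    ri, ci = int(round(rc[0])), int(round(rc[1]))
    r_lo, r_hi = max(ri - win, 0), min(ri + win + 1, img.shape[0])
    c_lo, c_hi = max(ci - win, 0), min(ci + win + 1, img.shape[1])
    patch = img[r_lo:r_hi, c_lo:c_hi].astype(float)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    bg = float(np.median(np.concatenate([patch[0, :], patch[-1, :], patch[:, 0], patch[:, -1]])))
    amp = max(float(patch.max()) - bg, 1e-9)
    R0 = max(0.6 * win, 2.0)

    def model(p):
        r0_, c0_, a, R, b = p
        d2 = (rr - r0_) ** 2 + (cc - c0_) ** 2
        return b + a * np.sqrt(np.maximum(R**2 - d2, 0.0))

    def resid(p):
        return (model(p) - patch).ravel()

    try:
        sol = _lsq(
            resid,
            np.array([rc[0], rc[1], amp / R0, R0, bg]),
            method="lm",
            max_nfev=400,
        )
        fit_rc = sol.x[:2]
        if np.linalg.norm(fit_rc - rc) < win:  # reject runaway fits
            rc = fit_rc
    except Exception:
        pass
    return rc


def detect_markers_2d(
    img,
    radius_range=(2.0, 8.0),
    max_detections: int | None = None,
    threshold_rel: float = 0.1,
) -> Detection2D:
    """Scale-space blob detection of bright sphere markers with subpixel
    centroid refinement.

    The image is flattened by subtracting a wide Gaussian background before
    LoG blob detection, which suppresses the smooth soft-tissue and bone
    shading that markers sit on.  Detections closer than one marker
    diameter are merged (strongest wins).  An empty result is allowed.
    """
    a = np.asarray(getattr(img, "values", img), dtype=float)
    if radius_range[0] <= 0 or radius_range[1] <= radius_range[0]:
        raise ValueError("radius range must be positive and increasing")
    flat = a - ndimage.gaussian_filter(a, sigma=3.0 * radius_range[1])
    span = float(flat.max() - flat.min())
    if span <= 0:
        return Detection2D(np.empty((0, 2)), np.empty(0), np.empty(0))
    norm = (flat - flat.min()) / span
    blobs = blob_log(
        norm,
        min_sigma=radius_range[0] / np.sqrt(2.0),
        max_sigma=radius_range[1] / np.sqrt(2.0),
        num_sigma=8,
        threshold=threshold_rel * 0.1,
    )
    if blobs.size == 0:
        return Detection2D(np.empty((0, 2)), np.empty(0), np.empty(0))

    cands = []
    for r0, c0, sig in blobs:
        radius = float(np.sqrt(2.0) * sig)
        win = max(int(np.ceil(1.6 * radius)), 3)
        rc = _refine_centroid(flat, r0, c0, win)
        # response: background-subtracted peak at the refined center
        ri, ci = int(round(rc[0])), int(round(rc[1]))
        ri = np.clip(ri, 0, a.shape[0] - 1)
        ci = np.clip(ci, 0, a.shape[1] - 1)
        cands.append((float(flat[ri, ci]), rc, radius))
    cands.sort(key=lambda t: -t[0])

    kept = []
    for resp, rc, radius in cands:
        if any(np.linalg.norm(rc - k[1]) < 2.0 * max(radius, k[2]) for k in kept):
            continue
        kept.append((resp, rc, radius))
        if max_detections is not None and len(kept) == max_detections:
            break
    return Detection2D(
        np.array([k[1] for k in kept]),
        np.array([k[0] for k in kept]),
        np.array([k[2] for k in kept]),
    )


def _rays(g: ProjectionGeometry, centroids: np.ndarray):
    pts = g.pixel_to_world(centroids)
    d = pts - g.source
    u = d / np.linalg.norm(d, axis=1)[:, None]
    return g.source, u


def _triangulate(o1, u1, o2, u2):
    """Midpoint triangulation of ray pairs.  Returns (points, gaps, t1, t2)
    where ``gaps`` are the closest-approach distances between the rays."""
    b = np.sum(u1 * u2, axis=1)
    w0 = o1 - o2
    a1 = u1 @ w0 if w0.ndim == 1 else np.sum(u1 * w0, axis=1)
    a2 = u2 @ w0 if w0.ndim == 1 else np.sum(u2 * w0, axis=1)
    den = 1.0 - b**2
    den = np.where(np.abs(den) < 1e-12, 1e-12, den)
    t1 = (b * a2 - a1) / den
    t2 = (a2 - b * a1) / den
    p1 = o1 + t1[:, None] * u1
    p2 = o2 + t2[:, None] * u2
    mid = (p1 + p2) / 2.0
    gaps = np.linalg.norm(p1 - p2, axis=1)
    return mid, gaps, p1, p2


def match_markers(
    d1: Detection2D,
    d2: Detection2D,
    g1: ProjectionGeometry,
    g2: ProjectionGeometry,
    max_residual_mm: float | None = None,
):
    """Marker correspondence between the two views.

    Scores every pairing by the closest-approach (triangulation) residual of
    the two back-projected rays under the nominal geometries and solves the
    assignment that minimizes the total residual.  Returns a list of
    ``(index_in_view1, index_in_view2)`` sorted by the first index.
    """
    if d1.count < 5 or d2.count < 5:
        raise ValueError(
            f"at least 5 detected markers per view are required ({d1.count} / {d2.count} found)"
        )
    o1, U1 = _rays(g1, d1.centroids)
    o2, U2 = _rays(g2, d2.centroids)
    n1, n2 = d1.count, d2.count
    cost = np.empty((n1, n2))
    for i in range(n1):
        u1 = np.broadcast_to(U1[i], U2.shape)
        _, gaps, _, _ = _triangulate(o1, u1, o2, U2)
        cost[i] = gaps
    ri, ci = linear_sum_assignment(cost)
    pairs = [(int(i), int(j)) for i, j in zip(ri, ci)]
    res = cost[ri, ci]
    if max_residual_mm is not None and np.mean(res) > max_residual_mm:
        raise ValueError(
            f"no geometrically consistent marker assignment found "
            f"(mean triangulation residual {np.mean(res):.2f} mm)"
        )
    pairs.sort(key=lambda p: p[0])
    return pairs


def estimate_relative_pose(
    d1: Detection2D,
    d2: Detection2D,
    matches,
    g1: ProjectionGeometry,
    g2_nominal: ProjectionGeometry,
    model_points=None,
    max_iter: int = 500,
    tol_mm: float = 1e-10,
    return_info: bool = False,
):
    """Refine the nominal view-1 -> view-2 relative pose from matched
    marker detections.

    Initialization is an alternating scheme: (i) triangulate the matched
    rays into a 3D marker point set under the current geometries; (ii)
    take, per marker, the closest point on each view's ray to the model
    point and rigidly align the view-2-consistent set onto the
    view-1-consistent set with the Umeyama closed form; (iii) move the
    view-2 camera by that transform.  A least-squares polish follows.

    ``model_points`` is the known 3D constellation of the (hybrid,
    optically tracked) markers, in any rigid frame.  When given, the polish
    aligns this rigid model to the scene (Umeyama-initialized) and refines
    {model alignment, view-2 camera} jointly under pixel reprojection error
    — the rigidity of the model is what makes the inter-view angulation
    well conditioned when the markers span little depth.  Without a model
    the scene points are free, which is noticeably noisier.

    Returns the refined :class:`RelativePose` (and an info dict with the
    triangulated points, reprojection RMS and flags when ``return_info``).
    """
    if len(matches) < 5:
        raise ValueError("at least 5 matched marker pairs are required")
    i1 = [m[0] for m in matches]
    i2 = [m[1] for m in matches]
    # identical views with identical detections: rays coincide pairwise and
    # triangulation is undefined; the relative pose is exactly the identity
    if (
        np.allclose(g1.source, g2_nominal.source, atol=1e-9)
        and np.allclose(g1.detector_center, g2_nominal.detector_center, atol=1e-9)
        and np.allclose(d1.centroids[i1], d2.centroids[i2], atol=1e-9)
    ):
        rel = relative_angulation(g1, g2_nominal)
        if return_info:
            return rel, {
                "model_points_mm": None,
                "triangulation_rms_mm": 0.0,
                "alignment_rms_mm": 0.0,
                "refined_geometry2": g2_nominal,
                "converged": True,
                "flags": {"identical_views": True},
            }
        return rel

    o1, U1 = _rays(g1, d1.centroids[i1])
    g2 = g2_nominal
    prev_rms = np.inf
    converged = False
    for _ in range(min(max_iter, 25)):
        o2, U2 = _rays(g2, d2.centroids[i2])
        X, gaps, p1, p2 = _triangulate(o1, U1, o2, U2)
        # closest point on each ray to the current model point
        a = o1 + (np.sum((X - o1) * U1, axis=1))[:, None] * U1
        b = o2 + (np.sum((X - o2) * U2, axis=1))[:, None] * U2
        T, rms = umeyama_align(b, a)
        Rm, tm = T["rotation"], T["translation"]
        from dataclasses import replace as _replace

        g2 = _replace(
            g2,
            source=Rm @ g2.source + tm,
            detector_center=Rm @ g2.detector_center + tm,
            row_dir=Rm @ g2.row_dir,
            col_dir=Rm @ g2.col_dir,
        )
        if abs(prev_rms - rms) < tol_mm:
            break
        prev_rms = rms

    # The alternation above contracts only linearly, so finish with a
    # two-view bundle adjustment: jointly refine the 6 view-2 camera
    # correction parameters (rotation vector about the camera center +
    # translation) and the 3D marker points, minimizing pixel reprojection
    # error in both views.  View 1 stays fixed (it defines the frame); the
    # baseline-magnitude direction is unobservable from correspondences and
    # is pinned at its nominal initialization by a weak Tikhonov term.
    from scipy.optimize import least_squares
    from scipy.spatial.transform import Rotation as _Rot
    from dataclasses import replace as _replace

    def _project(g, pts):
        # pinhole projection with the depth clamped away from zero so the
        # optimizer can recover from wild intermediate iterates
        v = pts - g.source
        depth = np.maximum(v @ g.axis, 1e-3)
        hit = g.source + v * (g.sdd / depth)[:, None]
        w = hit - g.detector_center
        rc = np.stack([w @ g.row_dir, w @ g.col_dir], axis=1)
        return rc / g.pixel_pitch + g.principal_point

    ref = g2.source.copy()
    g2_base = g2
    n = len(i1)
    rc1 = d1.centroids[i1]
    rc2 = d2.centroids[i2]

    def _geom(p):
        R = _Rot.from_rotvec(p[:3]).as_matrix()
        mv = lambda x: R @ (x - ref) + ref + p[3:]
        return _replace(
            g2_base,
            source=mv(g2_base.source),
            detector_center=mv(g2_base.detector_center),
            row_dir=R @ g2_base.row_dir,
            col_dir=R @ g2_base.col_dir,
        )

    o2_0, U2_0 = _rays(g2_base, rc2)
    X0, _, _, _ = _triangulate(o1, U1, o2_0, U2_0)
    reg_scale = np.array([0.1, 0.1, 0.1, 50.0, 50.0, 50.0])

    if model_points is not None:
        model = np.asarray(model_points, dtype=float)
        # model -> matched-detection correspondence via assignment against
        # the triangulated scene, refined once through a Umeyama alignment
        from scipy.optimize import linear_sum_assignment as _lsa

        dist = np.linalg.norm(model[:, None, :] - X0[None, :, :], axis=2)
        mi, xi = _lsa(dist)
        order = np.empty(n, dtype=int)
        order[xi] = mi
        T0, _ = umeyama_align(model[order], X0)
        M = model[order]

        def _alignment(a):
            R = _Rot.from_rotvec(a[:3]).as_matrix()
            return M @ (R @ T0["rotation"]).T + (R @ T0["translation"] + a[3:])

        def _residual(p):
            cam, al = p[:6], p[6:]
            pts = _alignment(al)
            r1 = (_project(g1, pts) - rc1).ravel()
            r2 = (_project(_geom(cam), pts) - rc2).ravel()
            return np.concatenate([r1, r2, 1e-3 * cam / reg_scale])

        p0 = np.zeros(12)
    else:

        def _residual(p):
            cam, pts = p[:6], p[6:].reshape(n, 3)
            r1 = (_project(g1, pts) - rc1).ravel()
            r2 = (_project(_geom(cam), pts) - rc2).ravel()
            return np.concatenate([r1, r2, 1e-3 * cam / reg_scale])

        p0 = np.concatenate([np.zeros(6), X0.ravel()])

    sol = least_squares(_residual, p0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=400 * p0.size)
    g2 = _geom(sol.x[:6])
    prev_rms = float(np.sqrt(np.mean(sol.fun[: 4 * n] ** 2)))
    converged = bool(sol.status > 0)
    if not converged and prev_rms > 1.0:
        raise RuntimeError("relative-pose refinement did not converge")

    # degeneracy diagnostics on the final triangulated model
    o2, U2 = _rays(g2, d2.centroids[i2])
    X, gaps, _, _ = _triangulate(o1, U1, o2, U2)
    sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    flags = {}
    if sv[1] < 1e-6 * max(sv[0], 1.0):
        raise ValueError("degenerate marker configuration (collinear markers)")
    if sv[2] < 1e-3 * sv[0]:
        # markers lie (near) a plane; flag if the baseline is in that plane
        normal = np.linalg.svd(X - X.mean(axis=0))[2][2]
        baseline = g2.source - g1.source
        nb = np.linalg.norm(baseline)
        if nb > 0 and abs(normal @ baseline) / nb < 0.1:
            flags["coplanar_with_baseline"] = True
    rel = relative_angulation(g1, g2)
    if return_info:
        info = {
            "model_points_mm": X,
            "triangulation_rms_mm": float(np.sqrt(np.mean(gaps**2))),
            "alignment_rms_mm": float(prev_rms),
            "refined_geometry2": g2,
            "converged": converged,
            "flags": flags,
        }
        return rel, info
    return rel
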
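"""Gradient-difference similarity between a fluoroscopic image and a DRR.

The measure compares vertical and horizontal image derivatives after
removing an unknown intensity scale ``s`` between the two modalities:

    S = sum_ij  A_v / (A_v + I_diffV(i,j)^2)  +  A_h / (A_h + I_diffH(i,j)^2)

with I_diffV = dI_fl/di - s * dI_DRR/di and I_diffH likewise in j.  Each
per-pixel term has the 1/(1+x^2) form, so it lies in (0, 1]: S is bounded by
twice the number of ROI pixels and attains that bound exactly when both
difference images vanish.  ``A_v`` and ``A_h`` set the gradient magnitude at
which similarity has dropped to one half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = [
    "SimilarityConfig",
    "gradient_images",
    "estimate_scale",
    "gradient_difference_similarity",
    "vertebra_roi",
]


@dataclass
class SimilarityConfig:
    """Constants of the similarity measure.

    ``A_v``/``A_h`` may be positive floats or ``"auto"``, in which case they
    default to the squared median absolute fluoro gradient over the ROI
    (a data-driven soft threshold that keeps the per-pixel normalization
    meaningful across noise levels).  ``s`` is either a fixed float or
    ``"estimate"`` for the least-squares closed form per evaluation.
    """

    A_v: Union[float, str] = "auto"
    A_h: Union[float, str] = "auto"
    s: Union[float, str] = "estimate"
    roi: Optional[np.ndarray] = None

    def __post_init__(self):
        for name, a in (("A_v", self.A_v), ("A_h", self.A_h)):
            if not (a == "auto" or (np.isscalar(a) and a > 0)):
                raise ValueError(f"{name} must be positive or 'auto'")
        if not (self.s == "estimate" or np.isscalar(self.s)):
            raise ValueError("s must be a number or 'estimate'")


def gradient_images(img: np.ndarray):
    """Central-difference derivatives ``(dI/di, dI/dj)`` (vertical along
    rows i, horizontal along columns j) with replicate borders."""
    a = np.asarray(img, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    p = np.pad(a, 1, mode="edge")
    gi = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    gj = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    return gi, gj


def estimate_scale(fl_grads, drr_grads, roi: Optional[np.ndarray] = None):
    """Closed-form least-squares intensity scale ``s`` minimizing
    ``sum (grad_fl - s * grad_drr)^2`` over the ROI, both directions pooled.

    Returns ``(s, degenerate)``; for an all-zero DRR gradient the problem is
    degenerate and ``(1.0, True)`` is returned.
    """
    gf = np.concatenate([np.asarray(g, dtype=float)[_roi_index(g, roi)].ravel() for g in fl_grads])
    gd = np.concatenate([np.asarray(g, dtype=float)[_roi_index(g, roi)].ravel() for g in drr_grads])
    if gf.shape != gd.shape:
        raise ValueError("gradient stacks must have the same shape")
    denom = float(gd @ gd)
    if denom <= 0.0:
        return 1.0, True
    return float(gf @ gd) / denom, False


def _roi_index(img: np.ndarray, roi: Optional[np.ndarray]):
    if roi is None:
        return np.s_[:, :]
    roi = np.asarray(roi)
    if roi.shape != img.shape:
        raise ValueError("ROI mask must match the image shape")
    return roi.astype(bool)


def gradient_difference_similarity(
    fluoro, drr, cfg: SimilarityConfig = SimilarityConfig()
) -> float:
    """Similarity S between a fluoro image and a DRR (larger = better;
    maximum ``2 * N_roi`` reached iff the scaled gradients agree exactly)."""
    fl = np.asarray(getattr(fluoro, "values", fluoro), dtype=float)
    dr = np.asarray(getattr(drr, "values", drr), dtype=float)
    if fl.shape != dr.shape:
        raise ValueError("fluoro and DRR must have the same shape")
    gfi, gfj = gradient_images(fl)
    gdi, gdj = gradient_images(dr)
    sel = _roi_index(fl, cfg.roi)

    if cfg.s == "estimate":
        s, _ = estimate_scale((gfi, gfj), (gdi, gdj), cfg.roi)
    else:
        s = float(cfg.s)

    dv = gfi[sel] - s * gdi[sel]
    dh = gfj[sel] - s * gdj[sel]

    def _resolve(a):
        if a == "auto":
            med = float(np.median(np.abs(np.concatenate([gfi[sel].ravel(), gfj[sel].ravel()]))))
            return med**2 if med > 0 else 1.0
        return float(a)

    A_v, A_h = _resolve(cfg.A_v), _resolve(cfg.A_h)
    S = float(np.sum(A_v / (A_v + dv**2)) + np.sum(A_h / (A_h + dh**2)))
    return S


def vertebra_roi(g, vertebra, volume, pose, dilation_px: int = 5) -> np.ndarray:
    """Boolean detector mask: the projected bounding box of a vertebra's
    mask under ``pose``, dilated by ``dilation_px`` — the support region
    over which that vertebra is matched."""
    from .geometry import project_points, apply_pose

    bbox = vertebra.mask_bbox_world(volume)
    corners = np.array([[bbox[i, 0], bbox[j, 1], bbox[k, 2]] for i in (0, 1) for j in (0, 1) for k in (0, 1)])
    rc = project_points(g, apply_pose(pose, corners))
    rows, cols = g.detector_shape
    r0 = max(int(np.floor(rc[:, 0].min())) - dilation_px, 0)
    r1 = min(int(np.ceil(rc[:, 0].max())) + dilation_px, rows - 1)
    c0 = max(int(np.floor(rc[:, 1].min())) - dilation_px, 0)
    c1 = min(int(np.ceil(rc[:, 1].max())) + dilation_px, cols - 1)
    roi = np.zeros((rows, cols), dtype=bool)
    roi[r0 : r1 + 1, c0 : c1 + 1] = True
    return roi
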
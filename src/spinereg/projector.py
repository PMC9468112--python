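"""DRR formation and fluoroscopy simulation.

The forward projector is ray-driven: for every detector pixel it integrates
the (optionally masked, optionally posed) attenuation volume along the
source->pixel ray with trilinear sampling at a fixed step (default half the
smallest voxel).  Images live in the line-integral (log-like) domain, where
the projector is exactly linear in the volume; the simulated fluoroscopy
adds Poisson-like and Gaussian noise plus an affine intensity change so that
the similarity measure's scale factor has something to absorb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .geometry import ProjectionGeometry, RigidPose, project_points
from .phantom import VolumeImage, MarkerModel, NoiseConfig

__all__ = ["DRRImage", "FluoroImage", "forward_project", "render_markers", "simulate_fluoro"]

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap

_CHUNK = 4096  # rays per chunk in the fallback path


@njit(cache=True, fastmath=True)
def _integrate_rays(vol, o, U, tnear, nsteps, step, origin, spacing, out):
    """Accumulate trilinear line integrals: for ray i, samples start at
    ``tnear[i] + step/2`` from the common origin ``o`` along direction
    ``U[i]``; positions outside the grid contribute zero."""
    nx, ny, nz = vol.shape
    for i in range(U.shape[0]):
        acc = 0.0
        ux, uy, uz = U[i, 0], U[i, 1], U[i, 2]
        for k in range(nsteps[i]):
            t = tnear[i] + (k + 0.5) * step
            fx = (o[0] + t * ux - origin[0]) / spacing[0]
            fy = (o[1] + t * uy - origin[1]) / spacing[1]
            fz = (o[2] + t * uz - origin[2]) / spacing[2]
            x0 = int(np.floor(fx))
            y0 = int(np.floor(fy))
            z0 = int(np.floor(fz))
            if x0 < -1 or x0 >= nx or y0 < -1 or y0 >= ny or z0 < -1 or z0 >= nz:
                continue
            dx = fx - x0
            dy = fy - y0
            dz = fz - z0
            for cx in range(2):
                xi = x0 + cx
                if xi < 0 or xi >= nx:
                    continue
                wx = dx if cx == 1 else 1.0 - dx
                for cy in range(2):
                    yi = y0 + cy
                    if yi < 0 or yi >= ny:
                        continue
                    wy = dy if cy == 1 else 1.0 - dy
                    for cz in range(2):
                        zi = z0 + cz
                        if zi < 0 or zi >= nz:
                            continue
                        wz = dz if cz == 1 else 1.0 - dz
                        acc += wx * wy * wz * vol[xi, yi, zi]
        out[i] = acc * step


@dataclass
class DRRImage:
    """Digitally reconstructed radiograph: line integrals on the detector."""

    values: np.ndarray
    geometry: ProjectionGeometry

    @property
    def pixel_pitch(self) -> float:
        return self.geometry.pixel_pitch


@dataclass
class FluoroImage:
    """A 2D fluoroscopy-like image.  ``geometry`` is the true geometry for
    simulated images and may be None for external inputs."""

    values: np.ndarray
    geometry: Optional[ProjectionGeometry] = None
    pixel_pitch: Optional[float] = None
    provenance: str = "simulated"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.geometry is not None:
            if self.pixel_pitch is None:
                self.pixel_pitch = self.geometry.pixel_pitch
            if tuple(self.values.shape) != tuple(self.geometry.detector_shape):
                raise ValueError("image size does not match the geometry's detector size")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image intensities must be finite")


def _pixel_grid(g: ProjectionGeometry, roi=None):
    rows, cols = g.detector_shape
    rsl = roi[0] if roi is not None else slice(0, rows)
    csl = roi[1] if roi is not None else slice(0, cols)
    rr = np.arange(rows)[rsl]
    cc = np.arange(cols)[csl]
    pr, pc = g.principal_point
    R, C = np.meshgrid(rr, cc, indexing="ij")
    off_r = (R - pr) * g.pixel_pitch
    off_c = (C - pc) * g.pixel_pitch
    pts = (
        g.detector_center
        + off_r[..., None] * g.row_dir
        + off_c[..., None] * g.col_dir
    )
    return rr, cc, pts.reshape(-1, 3)


def forward_project(
    volume: VolumeImage,
    g: ProjectionGeometry,
    pose: Optional[RigidPose] = None,
    mask: Optional[np.ndarray] = None,
    step: Optional[float] = None,
    roi=None,
) -> DRRImage:
    """Ray-driven DRR of ``volume`` (optionally restricted to a boolean
    ``mask``) under a rigid ``pose`` of the volume.

    Parameters
    ----------
    pose : rigid transform applied to the volume (rays are inverse-mapped
        into the volume frame, so no resampling of the volume occurs).
    mask : boolean array of the volume's shape; integrates ``volume * mask``.
    step : sampling step along the ray in mm (default half the smallest voxel).
    roi : optional ``(row_slice, col_slice)``; pixels outside stay zero.
    """
    if step is None:
        step = 0.5 * float(np.min(volume.spacing))
    if step <= 0:
        raise ValueError("step must be positive")
    if pose is not None and not np.all(np.isfinite(pose.params)):
        raise ValueError("pose must be finite")

    vals = volume.values
    sub_origin = volume.origin
    if mask is not None:
        if mask.shape != vals.shape:
            raise ValueError("mask shape must match the volume")
        idx = np.nonzero(mask)
        if len(idx[0]) == 0:
            return DRRImage(np.zeros(g.detector_shape), g)
        lo = np.array([i.min() for i in idx])
        hi = np.array([i.max() for i in idx]) + 1
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        vals = vals[sl] * mask[sl]
        sub_origin = volume.origin + lo * volume.spacing
    arr = np.ascontiguousarray(vals, dtype=np.float64)

    # source inside the sampled box is a degenerate geometry
    box_lo = sub_origin - volume.spacing
    box_hi = sub_origin + (np.array(arr.shape) - 1) * volume.spacing + volume.spacing
    if pose is not None:
        Rt = pose.matrix.T
        src_vol = Rt @ (g.source - pose.center - pose.translation) + pose.center
    else:
        src_vol = g.source
    if np.all(src_vol > box_lo) and np.all(src_vol < box_hi):
        raise ValueError("degenerate geometry: source lies inside the volume")

    rr, cc, pix = _pixel_grid(g, roi)
    out = np.zeros(g.detector_shape, dtype=np.float64)
    spacing = volume.spacing

    d = pix - g.source
    L = np.linalg.norm(d, axis=1)
    u = d / L[:, None]
    if pose is not None:
        o = src_vol
        uu = u @ pose.matrix  # R^T applied to each direction
    else:
        o = g.source
        uu = u
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / uu
        t1 = (box_lo - o) * inv
        t2 = (box_hi - o) * inv
    tlo = np.minimum(t1, t2)
    thi = np.maximum(t1, t2)
    tlo[~np.isfinite(tlo)] = -np.inf
    thi[~np.isfinite(thi)] = np.inf
    tnear = np.maximum(tlo.max(axis=1), 0.0)
    tfar = np.minimum(thi.min(axis=1), L)
    # snap sample positions to a global grid anchored at the source so that
    # decompositions of one volume (masks + background) sample identically
    # and therefore add up exactly
    tnear = np.maximum(np.floor(tnear / step) * step, 0.0)
    span = np.maximum(tfar - tnear, 0.0)
    nsteps = np.ceil(span / step).astype(np.int64)

    flat = np.zeros(pix.shape[0])
    if _HAVE_NUMBA:
        _integrate_rays(
            arr,
            np.ascontiguousarray(o, dtype=np.float64),
            np.ascontiguousarray(uu, dtype=np.float64),
            tnear,
            nsteps,
            float(step),
            np.ascontiguousarray(sub_origin, dtype=np.float64),
            np.ascontiguousarray(spacing, dtype=np.float64),
            flat,
        )
    else:  # vectorized fallback
        for start in range(0, pix.shape[0], _CHUNK):
            sl = slice(start, start + _CHUNK)
            ns = nsteps[sl]
            if ns.max(initial=0) == 0:
                continue
            ts = tnear[sl, None] + (np.arange(ns.max()) + 0.5) * step
            alive = np.arange(ns.max())[None, :] < ns[:, None]
            w = o + uu[sl, None, :] * ts[..., None]
            ijk = (w - sub_origin) / spacing
            samp = ndimage.map_coordinates(
                arr, ijk.reshape(-1, 3).T, order=1, mode="constant", cval=0.0
            ).reshape(ts.shape)
            flat[sl] = (samp * alive).sum(axis=1) * step

    out[np.ix_(rr, cc)] = flat.reshape(len(rr), len(cc))
    return DRRImage(out, g)


def render_markers(g: ProjectionGeometry, m: MarkerModel, roi=None) -> DRRImage:
    """Analytic DRR increment of the sphere markers: each pixel receives
    ``2 * mu * sqrt(r^2 - d^2)`` where ``d`` is the ray–center distance
    (the exact chord length through a homogeneous sphere)."""
    rr, cc, pix = _pixel_grid(g, roi)
    d = pix - g.source
    L = np.linalg.norm(d, axis=1)
    u = d / L[:, None]
    out = np.zeros(g.detector_shape, dtype=np.float64)
    acc = np.zeros(pix.shape[0])
    r2 = m.radius**2
    for c in m.centers:
        v = c - g.source
        t = u @ v
        if (v @ g.axis) <= 0:
            raise ValueError("marker at or behind the source plane")
        d2 = float(v @ v) - t**2
        chord2 = np.maximum(r2 - d2, 0.0)
        acc += 2.0 * m.attenuation * np.sqrt(chord2) * (t > 0)
    out[np.ix_(rr, cc)] = acc.reshape(len(rr), len(cc))
    return DRRImage(out, g)


def simulate_fluoro(
    volume: VolumeImage,
    vertebrae,
    markers: Optional[MarkerModel],
    g: ProjectionGeometry,
    poses,
    noise: NoiseConfig = NoiseConfig(),
    seed: int = 0,
    step: Optional[float] = None,
    background_fill: Optional[float] = None,
) -> FluoroImage:
    """Simulate one fluoroscopic view.

    Each vertebra is projected under its own true pose (the perturbation is
    applied at projection time, never by resampling the volume); the
    non-vertebral background is projected unposed; markers are rendered
    analytically; then Poisson-like noise, Gaussian noise and the affine
    intensity change of ``noise`` are applied.

    ``background_fill`` is the attenuation left behind where a vertebra was
    lifted out of the background (default: the soft-tissue level) — leaving
    vacuum there would imprint spurious bone-shaped edges at the
    *unperturbed* vertebra outlines.
    """
    if len(vertebrae) != len(poses):
        raise ValueError("need one pose per vertebra")
    if background_fill is None:
        from .phantom import MU_TISSUE

        background_fill = MU_TISSUE
    union = np.zeros(volume.shape, dtype=bool)
    for m in vertebrae:
        union |= m.mask
    bg = VolumeImage(
        np.where(union, np.float32(background_fill), volume.values),
        volume.spacing,
        volume.origin,
    )
    img = forward_project(bg, g, step=step).values
    for m, pose in zip(vertebrae, poses):
        img = img + forward_project(volume, g, pose=pose, mask=m.mask, step=step).values
    if markers is not None:
        img = img + render_markers(g, markers).values

    rng = np.random.default_rng(seed)
    if noise.gain > 0:
        img = img + rng.standard_normal(img.shape) * np.sqrt(noise.gain * np.maximum(img, 0.0))
    if noise.gaussian_sd > 0:
        img = img + rng.standard_normal(img.shape) * noise.gaussian_sd
    img = noise.intensity_scale * img + noise.intensity_offset
    return FluoroImage(img, geometry=g, provenance="simulated")
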
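"""Rigid poses, cone-beam projection geometry and point-set alignment.

Coordinate conventions
----------------------
All 3D quantities live in a single patient-aligned frame in millimetres:

* ``x`` — left–right (positive toward the patient's left),
* ``y`` — caudo-cranial (positive toward the head),
* ``z`` — fronto-dorsal (positive toward the back).

A :class:`RigidPose` is a 6-DOF transform ``q = (tx, ty, tz, wx, wy, wz)``
with translations in mm and rotations in degrees, applied extrinsically in
the order x -> y -> z about an explicit rotation center.  The rotation
center matters: per-vertebra poses rotate about the vertebral-body center
while coarse/global poses rotate about the volume center, which keeps
translation magnitudes comparable across vertebrae.

A :class:`ProjectionGeometry` is an ideal (distortion-free) cone-beam
camera: point source, flat detector orthogonal to the source->detector-center
ray, square pixels.  The C-arm angulation is a rotation of the whole camera
about the patient y-axis (longitudinal axis), 0 deg = anterior-posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidPose",
    "ProjectionGeometry",
    "RelativePose",
    "compose_pose",
    "invert_pose",
    "apply_pose",
    "umeyama_align",
    "project_points",
    "relative_angulation",
    "carm_geometry",
    "transform_geometry",
]

_CENTER_ATOL = 1e-9


def _as_vec3(x, name: str = "vector") -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be finite")
    return v


@dataclass(frozen=True)
class RigidPose:
    """6-DOF rigid transform: rotation (deg, extrinsic x->y->z) about
    ``center`` followed by translation (mm)."""

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "translation", _as_vec3(self.translation, "translation"))
        object.__setattr__(self, "rotation_deg", _as_vec3(self.rotation_deg, "rotation_deg"))
        object.__setattr__(self, "center", _as_vec3(self.center, "center"))

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidPose":
        return cls(np.zeros(3), np.zeros(3), np.asarray(center, dtype=float))

    @classmethod
    def from_params(cls, q, center=(0.0, 0.0, 0.0)) -> "RigidPose":
        """Build from the 6-vector ``q = (tx, ty, tz, wx, wy, wz)``."""
        q = np.asarray(q, dtype=float)
        if q.shape != (6,):
            raise ValueError("q must be a 6-vector (tx, ty, tz, wx, wy, wz)")
        return cls(q[:3], q[3:], np.asarray(center, dtype=float))

    @property
    def params(self) -> np.ndarray:
        """The 6-vector ``(tx, ty, tz, wx, wy, wz)``."""
        return np.concatenate([self.translation, self.rotation_deg])

    @property
    def matrix(self) -> np.ndarray:
        """Rotation matrix (extrinsic x->y->z order; lowercase scipy 'xyz')."""
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    def apply(self, points) -> np.ndarray:
        return apply_pose(self, points)

    def recenter(self, new_center) -> "RigidPose":
        """Equivalent pose expressed about a different rotation center."""
        new_center = _as_vec3(new_center, "new_center")
        R = self.matrix
        # p(x) = R(x - c) + c + t  ==  R(x - c') + c' + t'
        t_new = R @ (new_center - self.center) + self.center + self.translation - new_center
        return RigidPose(t_new, self.rotation_deg.copy(), new_center)

    def as_matrix4(self) -> np.ndarray:
        """Homogeneous 4x4 world-space matrix."""
        R = self.matrix
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = self.center + self.translation - R @ self.center
        return M


def apply_pose(pose: RigidPose, points) -> np.ndarray:
    """Apply a rigid pose to an (N, 3) array (or single 3-vector) of mm points."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 3:
        raise ValueError("points must have shape (N, 3)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    out = (pts - pose.center) @ pose.matrix.T + pose.center + pose.translation
    return out[0] if single else out


def _check_same_center(a: RigidPose, b: RigidPose) -> None:
    if not np.allclose(a.center, b.center, atol=1e-6):
        raise ValueError(
            "poses have different rotation centers; call .recenter() explicitly "
            f"({a.center} vs {b.center})"
        )


def compose_pose(a: RigidPose, b: RigidPose) -> RigidPose:
    """Pose equivalent to applying ``b`` first, then ``a`` (same center)."""
    _check_same_center(a, b)
    Ra, Rb = a.matrix, b.matrix
    R = Ra @ Rb
    angles = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
    t = Ra @ b.translation + a.translation
    return RigidPose(t, angles, a.center.copy())


def invert_pose(p: RigidPose) -> RigidPose:
    R = p.matrix
    angles = Rotation.from_matrix(R.T).as_euler("xyz", degrees=True)
    return RigidPose(-R.T @ p.translation, angles, p.center.copy())


def umeyama_align(src, dst, with_scale: bool = False):
    """Least-squares rigid (optionally similarity) alignment of corresponded
    point sets, closed form via SVD with the determinant sign correction.

    Parameters
    ----------
    src, dst : (N, 3) arrays, N >= 3, in correspondence.
    with_scale : if True also estimate an isotropic scale (similarity
        transform); default False because the registration problem is rigid.

    Returns
    -------
    transform : dict with keys ``rotation`` (3x3), ``translation`` (3,),
        ``scale`` (float) such that ``dst ~ scale * R @ src + t``.
    rms : float, root-mean-square residual in mm.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must both be (N, 3) with matching N")
    n = src.shape[0]
    if n < 3:
        raise ValueError("need at least 3 corresponded points")

    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / n
    U, d, Vt = np.linalg.svd(cov)
    # rank < 2 => points (near-)collinear: rotation about the line is free
    if d[1] <= max(1e-12, 1e-9 * d[0]):
        raise ValueError("degenerate (collinear or coincident) point configuration")
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    if with_scale:
        var_s = (xs**2).sum() / n
        scale = float(np.trace(np.diag(d) @ S) / var_s)
    else:
        scale = 1.0
    t = mu_d - scale * R @ mu_s
    resid = dst - (scale * src @ R.T + t)
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return {"rotation": R, "translation": t, "scale": scale}, rms


@dataclass(frozen=True)
class ProjectionGeometry:
    """Ideal cone-beam camera (point source, flat orthogonal detector).

    ``row_dir``/``col_dir`` span the detector plane (unit vectors along
    increasing row / column index); pixel (0, 0) is the first row/column
    and coordinates follow the pixel-center convention, so the principal
    point (central ray) is at ``((rows-1)/2, (cols-1)/2)``.
    """

    source: np.ndarray
    detector_center: np.ndarray
    row_dir: np.ndarray
    col_dir: np.ndarray
    pixel_pitch: float
    detector_shape: tuple  # (rows, cols)
    sdd: float
    sod: float
    angulation_deg: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "source", _as_vec3(self.source, "source"))
        object.__setattr__(self, "detector_center", _as_vec3(self.detector_center, "detector_center"))
        object.__setattr__(self, "row_dir", _as_vec3(self.row_dir, "row_dir"))
        object.__setattr__(self, "col_dir", _as_vec3(self.col_dir, "col_dir"))
        object.__setattr__(self, "detector_shape", (int(self.detector_shape[0]), int(self.detector_shape[1])))
        if not (self.sdd > self.sod > 0):
            raise ValueError("require SDD > SOD > 0")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel pitch must be positive")
        ax = self.axis
        for name, v in (("row_dir", self.row_dir), ("col_dir", self.col_dir)):
            if abs(np.linalg.norm(v) - 1) > 1e-8:
                raise ValueError(f"{name} must be a unit vector")
            if abs(v @ ax) > 1e-8:
                raise ValueError(f"{name} must be orthogonal to the projection axis")
        if abs(self.row_dir @ self.col_dir) > 1e-8:
            raise ValueError("row_dir and col_dir must be orthogonal")

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from source toward detector center."""
        v = self.detector_center - self.source
        return v / np.linalg.norm(v)

    @property
    def principal_point(self) -> np.ndarray:
        rows, cols = self.detector_shape
        return np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])

    @property
    def isocenter(self) -> np.ndarray:
        return self.source + self.sod * self.axis

    def pixel_to_world(self, rc) -> np.ndarray:
        """World mm position of detector pixel coordinates (row, col)."""
        rc = np.atleast_2d(np.asarray(rc, dtype=float))
        off = (rc - self.principal_point) * self.pixel_pitch
        pts = self.detector_center + off[:, [0]] * self.row_dir + off[:, [1]] * self.col_dir
        return pts

    def to_dict(self) -> dict:
        return {
            "source_mm": self.source.tolist(),
            "detector_center_mm": self.detector_center.tolist(),
            "row_dir": self.row_dir.tolist(),
            "col_dir": self.col_dir.tolist(),
            "pixel_pitch_mm": self.pixel_pitch,
            "detector_shape": list(self.detector_shape),
            "sdd_mm": self.sdd,
            "sod_mm": self.sod,
            "angulation_deg": self.angulation_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionGeometry":
        return cls(
            source=np.array(d["source_mm"]),
            detector_center=np.array(d["detector_center_mm"]),
            row_dir=np.array(d["row_dir"]),
            col_dir=np.array(d["col_dir"]),
            pixel_pitch=float(d["pixel_pitch_mm"]),
            detector_shape=tuple(d["detector_shape"]),
            sdd=float(d["sdd_mm"]),
            sod=float(d["sod_mm"]),
            angulation_deg=float(d.get("angulation_deg", 0.0)),
        )

    def downsample(self, factor: int) -> "ProjectionGeometry":
        """Coarser-resolution detector covering the same physical plate."""
        rows, cols = self.detector_shape
        return replace(
            self,
            pixel_pitch=self.pixel_pitch * factor,
            detector_shape=(rows // factor, cols // factor),
        )


def carm_geometry(
    angulation_deg: float,
    sdd: float = 1000.0,
    sod: float = 750.0,
    pixel_pitch: float = 1.0,
    detector_shape=(256, 256),
    isocenter=(0.0, 0.0, 0.0),
) -> ProjectionGeometry:
    """Mobile C-arm geometry at a given latero-lateral angulation.

    At 0 deg (AP) the beam travels front-to-back (+z, toward the prone
    patient's dorsal side, where the skin markers and the detector sit).
    Positive angulation rotates the whole camera about the patient's
    longitudinal y-axis; the C-arm stays neutral cranio-caudally, so detector
    rows remain aligned with y.
    """
    iso = _as_vec3(isocenter, "isocenter")
    Ry = Rotation.from_euler("y", angulation_deg, degrees=True).as_matrix()
    axis = Ry @ np.array([0.0, 0.0, 1.0])
    col = Ry @ np.array([1.0, 0.0, 0.0])
    row = np.array([0.0, 1.0, 0.0])
    return ProjectionGeometry(
        source=iso - sod * axis,
        detector_center=iso + (sdd - sod) * axis,
        row_dir=row,
        col_dir=col,
        pixel_pitch=pixel_pitch,
        detector_shape=tuple(detector_shape),
        sdd=sdd,
        sod=sod,
        angulation_deg=angulation_deg,
    )


def project_points(g: ProjectionGeometry, points) -> np.ndarray:
    """Perspective projection of mm points onto the detector, in pixel
    coordinates (row, col), 0-based, pixel-center convention.

    Raises if any point is at or behind the source plane (depth along the
    projection axis <= 0).
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    v = pts - g.source
    ax = g.axis
    depth = v @ ax
    if np.any(depth <= 1e-9):
        raise ValueError("point at or behind the source plane cannot be projected")
    hit = g.source + v * (g.sdd / depth)[:, None]
    w = hit - g.detector_center
    rc_mm = np.stack([w @ g.row_dir, w @ g.col_dir], axis=1)
    rc = rc_mm / g.pixel_pitch + g.principal_point
    return rc[0] if single else rc


def transform_geometry(g: ProjectionGeometry, pose: RigidPose) -> ProjectionGeometry:
    """Rigidly move the whole camera by ``pose`` (moving-frame equivalence:
    projecting pose-moved points with ``g`` equals projecting the original
    points with ``transform_geometry(g, invert_pose(pose))``)."""
    R = pose.matrix
    return replace(
        g,
        source=apply_pose(pose, g.source),
        detector_center=apply_pose(pose, g.detector_center),
        row_dir=R @ g.row_dir,
        col_dir=R @ g.col_dir,
    )


@dataclass(frozen=True)
class RelativePose:
    """Rigid transform mapping view-1 camera geometry into view-2 geometry.

    ``rad_deg`` is the rotation angle difference (RAD) — the angle of the
    rotation part, which is symmetric under inversion of the transform.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", _as_vec3(self.translation, "translation"))

    @property
    def rad_deg(self) -> float:
        return float(np.degrees(Rotation.from_matrix(self.rotation).magnitude()))

    def inverse(self) -> "RelativePose":
        return RelativePose(self.rotation.T, -self.rotation.T @ self.translation)

    def apply_to_geometry(self, g: ProjectionGeometry) -> ProjectionGeometry:
        R = self.rotation
        mv = lambda p: R @ p + self.translation
        return replace(
            g,
            source=mv(g.source),
            detector_center=mv(g.detector_center),
            row_dir=R @ g.row_dir,
            col_dir=R @ g.col_dir,
        )

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation_mm": self.translation.tolist(),
            "rad_deg": self.rad_deg,
        }


def _camera_frame(g: ProjectionGeometry) -> np.ndarray:
    """Orthonormal camera basis as columns (col_dir, row_dir, axis)."""
    return np.stack([g.col_dir, g.row_dir, g.axis], axis=1)


def relative_angulation(g1: ProjectionGeometry, g2: ProjectionGeometry) -> RelativePose:
    """Rigid transform taking view-1 geometry onto view-2 geometry, with RAD.

    Both geometries must be expressed in the same patient frame.  RAD is the
    angle of the rotation part; for opposed angulations (-a, +a) about the
    longitudinal axis this equals 2a (e.g. -20/+20 -> 40 deg).
    """
    B1, B2 = _camera_frame(g1), _camera_frame(g2)
    R = B2 @ B1.T
    t = g2.source - R @ g1.source
    return RelativePose(R, t)
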
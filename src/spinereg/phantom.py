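"""Procedural spine phantom: synthetic CT-like volumes with labelled
vertebrae, analytic landmarks, skin-marker models and full simulated
fluoroscopy test cases.

The phantom stands in for a segmented baseline CT.  Vertebrae are stylized
(ellipsoidal body + posterior ring + two pedicle struts + spinous knob)
rather than anatomical: the registration machinery only needs structured
image gradients, and stylized shapes give exact analytic landmark ground
truth.  All shapes are voxelized with an anti-aliased (one-voxel smoothstep)
edge so that line integrals and image gradients are well behaved.

Every generator is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .geometry import RigidPose, ProjectionGeometry, carm_geometry, relative_angulation

__all__ = [
    "VolumeImage",
    "VertebraModel",
    "MarkerModel",
    "NoiseConfig",
    "CaseConfig",
    "TestCase",
    "make_phantom",
    "perturb_spine",
    "PerturbRanges",
    "place_markers",
    "resample_slice_thickness",
    "make_test_case",
]

# attenuation levels, 1/mm (order of magnitude of cortical bone / soft
# tissue at fluoroscopy energies; exact values are cosmetic)
MU_BONE = 0.030
MU_TISSUE = 0.005
MU_MARKER = 0.5

# canonical spine labels used to name a window of vertebrae around a
# centered level (thoracic T1..T12, lumbar L1..L5, sacral S1)
SPINE_LABELS = [f"T{i}" for i in range(1, 13)] + [f"L{i}" for i in range(1, 6)] + ["S1"]


@dataclass
class VolumeImage:
    """3D attenuation grid.  Array axes (0, 1, 2) follow the patient axes
    (x left-right, y caudo-cranial, z fronto-dorsal); ``origin`` is the
    world-mm position of the center of voxel (0, 0, 0)."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3D")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self):
        return self.values.shape

    @property
    def extent_mm(self) -> np.ndarray:
        return (np.array(self.shape) - 1) * self.spacing

    @property
    def center_mm(self) -> np.ndarray:
        return self.origin + self.extent_mm / 2.0

    def index_to_world(self, idx) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, xyz) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing


@dataclass
class VertebraModel:
    """One labelled vertebra: binary mask in the volume grid, the two TRE
    landmarks (vertebral-body center and left-pedicle center, world mm) and,
    once the spine is perturbed, its true intraoperative pose."""

    label: str
    mask: np.ndarray
    body_center: np.ndarray
    left_pedicle: np.ndarray
    true_pose: Optional[RigidPose] = None
    body_mask: Optional[np.ndarray] = None  # the ellipsoidal body only

    def __post_init__(self):
        self.body_center = np.asarray(self.body_center, dtype=float)
        self.left_pedicle = np.asarray(self.left_pedicle, dtype=float)

    def mask_bbox_world(self, volume: VolumeImage) -> np.ndarray:
        """(2, 3) world-mm min/max corners of the mask's bounding box."""
        idx = np.array(np.nonzero(self.mask))
        lo = volume.index_to_world(idx.min(axis=1))
        hi = volume.index_to_world(idx.max(axis=1))
        return np.stack([lo, hi])


@dataclass
class MarkerModel:
    """Radiopaque sphere markers on the dorsal skin surface."""

    centers: np.ndarray  # (N, 3) mm
    radius: float = 3.0
    attenuation: float = MU_MARKER

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.shape[0] < 5:
            raise ValueError(
                f"at least 5 skin markers are required for registration, got {self.centers.shape[0]}"
            )

    @property
    def count(self) -> int:
        return self.centers.shape[0]


@dataclass(frozen=True)
class PerturbRanges:
    """Half-widths of the uniform per-vertebra pose perturbation.

    Defaults cover the inter-vertebral motion the registration is expected
    to correct: up to 5 deg rotation about the x-axis and up to 2 mm
    translation along the z-axis; other components default to zero but are
    configurable.
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 2.0
    wx: float = 5.0
    wy: float = 0.0
    wz: float = 0.0

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.wx, self.wy, self.wz])


@dataclass(frozen=True)
class NoiseConfig:
    """Fluoroscopy degradation model, applied in the line-integral domain.

    ``gain`` scales signal-dependent (Poisson-like) noise, ``gaussian_sd``
    is additive detector noise, and the affine intensity map
    ``scale * I + offset`` emulates the unknown detector response that the
    similarity measure's scale factor ``s`` must absorb.
    """

    gain: float = 0.003
    gaussian_sd: float = 0.03
    intensity_scale: float = 1.3
    intensity_offset: float = 0.1

    def __post_init__(self):
        if self.gain < 0 or self.gaussian_sd < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class CaseConfig:
    """Factor space of one simulated test case.

    The defaults are the experiment's center point: 5 captured vertebrae,
    an opposed +/-30 deg angulation pair (RAD 60), 8 skin markers in a
    150x150 mm dorsal frame, 200 mm detector-skin distance, baseline
    0.67 mm slice spacing.
    """

    n_vertebrae: int = 5
    centered_label: str = "T7"
    shape: tuple = (96, 96, 96)
    spacing: tuple = (1.0, 0.67, 1.0)
    angulation_pair: tuple = (-30.0, 30.0)
    # the mobile C-arm is positioned by hand, so the realized second
    # angulation deviates from the nominal one; view 1 defines the reference
    # frame and is taken as exact
    angulation_jitter_deg: float = 2.0
    marker_count: int = 8
    marker_frame_mm: tuple = (150.0, 150.0)
    marker_radius_mm: float = 3.0
    detector_skin_mm: float = 200.0
    skin_offset_mm: float = 60.0  # dorsal skin plane height above the isocenter
    sdd_mm: float = 1000.0
    pixel_pitch_mm: float = 1.0
    detector_shape: tuple = (256, 256)
    slice_thickness_mm: Optional[float] = None  # resample if set
    soft_tissue_mu: float = MU_TISSUE
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    perturb: PerturbRanges = field(default_factory=PerturbRanges)

    def __post_init__(self):
        if self.marker_count < 5:
            raise ValueError("at least 5 skin markers are required")
        for a in self.angulation_pair:
            if abs(a) > 45.0:
                raise ValueError("C-arm angulation limited to +/-45 deg from AP")

    @property
    def sod_mm(self) -> float:
        # detector-skin distance is realised by shifting the source-object
        # distance: detector plate sits detector_skin_mm behind the skin plane
        return self.sdd_mm - self.detector_skin_mm - self.skin_offset_mm

    def geometry(self, angulation_deg: float, isocenter) -> ProjectionGeometry:
        return carm_geometry(
            angulation_deg,
            sdd=self.sdd_mm,
            sod=self.sod_mm,
            pixel_pitch=self.pixel_pitch_mm,
            detector_shape=self.detector_shape,
            isocenter=isocenter,
        )


@dataclass
class TestCase:
    """Everything one registration run consumes, plus all ground truth."""

    volume: VolumeImage
    vertebrae: list
    markers: MarkerModel
    fluoro1: "object"  # FluoroImage (projector module)
    fluoro2: "object"
    geometry1: ProjectionGeometry
    geometry2: ProjectionGeometry
    config: CaseConfig
    seed: int

    @property
    def true_relative_pose(self):
        return relative_angulation(self.geometry1, self.geometry2)

    @property
    def rad_deg(self) -> float:
        """Nominal (configured) rotation angle difference between the views."""
        return float(abs(self.config.angulation_pair[1] - self.config.angulation_pair[0]))

    @property
    def realized_rad_deg(self) -> float:
        """RAD actually realized by the (jittered) true geometries."""
        return self.true_relative_pose.rad_deg


def _smoothstep(d: np.ndarray, edge: float) -> np.ndarray:
    """Anti-aliased indicator: 1 inside (d<0), 0 outside, linear ramp of
    width ``edge`` across the boundary."""
    return np.clip(0.5 - d / edge, 0.0, 1.0)


def _label_window(centered: str, n: int) -> list:
    if centered not in SPINE_LABELS:
        raise ValueError(f"unknown vertebra label {centered!r}")
    ic = SPINE_LABELS.index(centered)
    lo = ic - (n - 1) // 2
    if lo < 0 or lo + n > len(SPINE_LABELS):
        raise ValueError(f"label window of {n} around {centered} leaves the spine")
    # cranial first (towards T1) so labels run cranio-caudally
    return SPINE_LABELS[lo : lo + n]


def make_phantom(
    n_vertebrae: int = 5,
    spacing=(1.0, 0.67, 1.0),
    shape=(96, 96, 96),
    seed: int = 0,
    centered_label: str = "T7",
    soft_tissue_mu: float = MU_TISSUE,
):
    """Build a stylized spine volume with ``n_vertebrae`` labelled vertebrae.

    Returns ``(VolumeImage, [VertebraModel, ...])`` with vertebrae ordered
    cranio-caudally.  Landmarks (body center, left pedicle center) are the
    analytic shape centers; masks are pairwise disjoint.  Deterministic in
    ``seed`` (shape/intensity jitter only).
    """
    if n_vertebrae < 2:
        raise ValueError("need at least 2 vertebrae")
    spacing = np.asarray(spacing, dtype=float)
    shape = tuple(int(s) for s in shape)
    extent = (np.array(shape) - 1) * spacing
    origin = -extent / 2.0  # volume centered on the world origin
    rng = np.random.default_rng(seed)

    # vertebra pitch along y, leaving a half-pitch margin at both ends
    pitch = extent[1] / n_vertebrae
    if pitch < 8 * max(spacing):
        raise ValueError("volume too small to hold the requested spine")
    y_centers = origin[1] + pitch * (np.arange(n_vertebrae) + 0.5)
    y_centers = y_centers[::-1]  # cranial (largest y) first

    # stylized proportions scale with the pitch
    body_sx, body_sy, body_sz = 0.58 * pitch, 0.38 * pitch, 0.42 * pitch
    body_z = -0.5 * pitch
    ring_R, ring_r = 0.42 * pitch, 0.16 * pitch
    ring_z = body_z + body_sz + ring_R * 0.9
    ped_x, ped_r = 0.40 * pitch, 0.15 * pitch
    ped_z = (body_z + body_sz + ring_z - ring_R) / 2.0
    spin_z = ring_z + ring_R + 0.18 * pitch

    X = origin[0] + spacing[0] * np.arange(shape[0])
    Y = origin[1] + spacing[1] * np.arange(shape[1])
    Z = origin[2] + spacing[2] * np.arange(shape[2])
    edge = float(np.max(spacing))

    vol = np.zeros(shape, dtype=np.float32)
    # soft-tissue torso: elliptic cylinder along y
    tis_a, tis_b = 0.47 * extent[0], 0.45 * extent[2]
    xx, zz = np.meshgrid(X, Z, indexing="ij")
    d_tis = np.sqrt((xx / tis_a) ** 2 + (zz / tis_b) ** 2) - 1.0
    tissue = _smoothstep(d_tis * min(tis_a, tis_b), edge).astype(np.float32)
    vol += soft_tissue_mu * tissue[:, None, :]

    models = []
    labels = _label_window(centered_label, n_vertebrae)
    for label, yc in zip(labels, y_centers):
        jx, jz = rng.uniform(-1.0, 1.0, 2)
        size_j = rng.uniform(0.92, 1.08)
        mu_j = MU_BONE * rng.uniform(0.9, 1.1)
        bc = np.array([jx, yc, body_z + jz])

        # evaluate on the vertebra's y-slab only
        ysel = np.abs(Y - yc) < 0.5 * pitch
        y = Y[ysel]
        gx, gy, gz = np.meshgrid(X, y, Z, indexing="ij")

        # ellipsoidal body
        sx, sy, sz = body_sx * size_j, body_sy, body_sz * size_j
        db = (
            np.sqrt(((gx - bc[0]) / sx) ** 2 + ((gy - yc) / sy) ** 2 + ((gz - bc[2]) / sz) ** 2)
            - 1.0
        ) * min(sx, sy, sz)
        body_aa = _smoothstep(db, edge)
        aa = body_aa

        # posterior ring (torus, axis along y)
        rad = np.sqrt((gx - jx) ** 2 + (gz - ring_z) ** 2)
        dr = np.sqrt((rad - ring_R) ** 2 + (gy - yc) ** 2) - ring_r
        aa = np.maximum(aa, _smoothstep(dr, edge))

        # pedicle struts (cylinders along z); +x is the patient's left
        for sgn in (+1.0, -1.0):
            dp = np.sqrt((gx - sgn * ped_x - jx) ** 2 + (gy - yc) ** 2) - ped_r
            inz = np.maximum(gz - (ring_z - ring_R * 0.2), (bc[2] + 0.2 * sz) - gz)
            dp = np.maximum(dp, inz - 0.5 * edge)
            aa = np.maximum(aa, _smoothstep(dp, edge))

        # spinous knob (breaks the dorsal symmetry)
        ds = (
            np.sqrt(
                ((gx - jx) / (0.18 * pitch)) ** 2
                + ((gy - yc) / (0.22 * pitch)) ** 2
                + ((gz - spin_z) / (0.28 * pitch)) ** 2
            )
            - 1.0
        ) * (0.18 * pitch)
        aa = np.maximum(aa, _smoothstep(ds, edge))

        sub = np.zeros(shape, dtype=np.float32)
        sub[:, ysel, :] = aa.astype(np.float32)
        vol = np.maximum(vol, mu_j * sub)

        mask = sub > 0.5
        bmask = np.zeros(shape, dtype=bool)
        bmask[:, ysel, :] = body_aa > 0.5
        models.append(
            VertebraModel(
                label=label,
                mask=mask,
                body_center=bc,
                left_pedicle=np.array([ped_x + jx, yc, ped_z]),
                body_mask=bmask,
            )
        )

    volume = VolumeImage(vol, spacing, origin)
    return volume, models


def perturb_spine(models, ranges: PerturbRanges = PerturbRanges(), seed: int = 0):
    """Assign each vertebra an independent true intraoperative pose, drawn
    uniformly within ``ranges`` about its own body center."""
    rng = np.random.default_rng(seed)
    half = ranges.as_array
    out = []
    for m in models:
        q = rng.uniform(-half, half)
        pose = RigidPose.from_params(q, center=m.body_center)
        out.append(replace(m, true_pose=pose))
    return out


def place_markers(
    count: int = 8,
    frame=(150.0, 150.0),
    seed: int = 0,
    radius: float = 3.0,
    skin_z: float = 60.0,
    center=(0.0, 0.0),
    attenuation: float = MU_MARKER,
    sagittal_drop: float = 25.0,
) -> MarkerModel:
    """Scatter ``count`` radiopaque spheres on the dorsal skin surface
    inside a ``frame`` (mm, x by y) centered above the centered vertebra.

    The surface is the convex back of a prone subject: highest over the
    midline, dropping ``sagittal_drop`` mm toward the lateral frame edges
    (plus small random relief).  This depth diversity matters: markers on a
    perfectly flat plane parallel to the inter-view baseline make the
    relative angulation unobservable from the images.  Centers are
    rejection-sampled to keep spheres separated by > 2 diameters.
    """
    if count < 5:
        raise ValueError("at least 5 skin markers are required for registration")
    rng = np.random.default_rng(seed)
    fx, fy = float(frame[0]) / 2.0, float(frame[1]) / 2.0
    min_sep = 4.0 * radius
    centers = []
    for _ in range(10000):
        if len(centers) == count:
            break
        x = center[0] + rng.uniform(-fx, fx)
        y = center[1] + rng.uniform(-fy, fy)
        z = skin_z - sagittal_drop * ((x - center[0]) / fx) ** 2 + rng.uniform(-2.0, 2.0)
        p = np.array([x, y, z])
        if all(np.linalg.norm(p[:2] - c[:2]) > min_sep for c in centers):
            centers.append(p)
    if len(centers) < count:
        raise RuntimeError("could not place markers with the requested separation")
    return MarkerModel(np.array(centers), radius=radius, attenuation=attenuation)


def resample_slice_thickness(volume: VolumeImage, thickness: float) -> VolumeImage:
    """Degrade the slice (y) spacing: slab-average over the new thickness,
    then linearly interpolate new slice centers.  World coordinates (and so
    all landmarks) are unchanged."""
    if thickness <= 0:
        raise ValueError("slice thickness must be positive")
    dy = volume.spacing[1]
    if thickness < dy - 1e-9:
        raise ValueError("new thickness must be >= the original slice spacing")
    if abs(thickness - dy) < 1e-9:
        return VolumeImage(volume.values.copy(), volume.spacing.copy(), volume.origin.copy())
    ratio = thickness / dy
    # slab averaging (partial-volume) over the new slice profile
    smoothed = ndimage.uniform_filter1d(volume.values.astype(np.float64), size=max(int(round(ratio)), 1), axis=1, mode="nearest")
    ny_new = int(np.floor((volume.shape[1] - 1) * dy / thickness)) + 1
    # keep the stack centered in the original extent
    old_span = (volume.shape[1] - 1) * dy
    new_span = (ny_new - 1) * thickness
    y0 = (old_span - new_span) / 2.0
    yi = (y0 + thickness * np.arange(ny_new)) / dy  # positions in old index units
    coords = np.broadcast_arrays(
        np.arange(volume.shape[0])[:, None, None].astype(float),
        yi[None, :, None],
        np.arange(volume.shape[2])[None, None, :].astype(float),
    )
    vals = ndimage.map_coordinates(smoothed, np.stack([c.ravel() for c in coords]), order=1).reshape(
        volume.shape[0], ny_new, volume.shape[2]
    )
    spacing = volume.spacing.copy()
    spacing[1] = thickness
    origin = volume.origin.copy()
    origin[1] = volume.origin[1] + y0
    return VolumeImage(vals.astype(np.float32), spacing, origin)


def _resample_mask(mask: np.ndarray, src: VolumeImage, dst: VolumeImage) -> np.ndarray:
    """Nearest-equivalent resampling of a binary mask onto another grid
    (linear interpolation of the indicator, thresholded at 0.5)."""
    as_vol = VolumeImage(mask.astype(np.float32), src.spacing, src.origin)
    res = resample_slice_thickness(as_vol, dst.spacing[1])
    return res.values > 0.5


def make_test_case(config: CaseConfig = CaseConfig(), seed: int = 0) -> TestCase:
    """Build a complete simulated registration case: phantom -> per-vertebra
    perturbation -> skin markers -> two simulated fluoroscopic views with
    true geometries.  Bit-reproducible in ``(config, seed)``."""
    from .projector import simulate_fluoro  # local import to avoid a cycle

    ss = np.random.SeedSequence(seed)
    s_phantom, s_perturb, s_markers, s_noise1, s_noise2, s_jitter = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)
    ]

    volume, models = make_phantom(
        n_vertebrae=config.n_vertebrae,
        spacing=config.spacing,
        shape=config.shape,
        seed=s_phantom,
        centered_label=config.centered_label,
        soft_tissue_mu=config.soft_tissue_mu,
    )
    models = perturb_spine(models, config.perturb, seed=s_perturb)
    ic = config.n_vertebrae // 2
    markers = place_markers(
        count=config.marker_count,
        frame=config.marker_frame_mm,
        seed=s_markers,
        radius=config.marker_radius_mm,
        skin_z=config.skin_offset_mm,
        center=(models[ic].body_center[0], models[ic].body_center[1]),
    )
    jit = np.random.default_rng(s_jitter).uniform(
        -config.angulation_jitter_deg, config.angulation_jitter_deg
    )
    g1 = config.geometry(config.angulation_pair[0], isocenter=(0.0, 0.0, 0.0))
    g2 = config.geometry(config.angulation_pair[1] + jit, isocenter=(0.0, 0.0, 0.0))
    poses = [m.true_pose for m in models]
    # fluoroscopy always comes from the full-resolution anatomy; a degraded
    # slice thickness affects only the baseline volume (and its masks) that
    # the registration consumes
    f1 = simulate_fluoro(volume, models, markers, g1, poses, config.noise, seed=s_noise1)
    f2 = simulate_fluoro(volume, models, markers, g2, poses, config.noise, seed=s_noise2)
    if config.slice_thickness_mm is not None:
        degraded = resample_slice_thickness(volume, config.slice_thickness_mm)
        models = [
            replace(
                m,
                mask=_resample_mask(m.mask, volume, degraded),
                body_mask=None if m.body_mask is None else _resample_mask(m.body_mask, volume, degraded),
            )
            for m in models
        ]
        volume = degraded
    return TestCase(
        volume=volume,
        vertebrae=models,
        markers=markers,
        fluoro1=f1,
        fluoro2=f2,
        geometry1=g1,
        geometry2=g2,
        config=config,
        seed=seed,
    )
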
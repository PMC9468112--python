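"""File I/O: volumes (NIfTI / DICOM series), images (TIFF + JSON geometry
sidecar), test-case bundles and result tables.

A test-case bundle is a self-describing directory:

    manifest.json     resolved configuration, seed, file inventory
    volume.nii        attenuation volume (axes = patient axes, mm)
    labels.nii        uint8 vertebra label map (1..n, cranio-caudal)
    fluoro1.tif/.json fluoroscopy image + geometry sidecar (idem fluoro2)
    landmarks.csv     per-vertebra landmarks and true poses
    markers.csv       sphere marker centers

Images are written as float32 TIFF by default so that a write/read
round-trip is bit-exact; 16-bit output is available for viewers.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .geometry import ProjectionGeometry, RigidPose
from .phantom import CaseConfig, MarkerModel, NoiseConfig, PerturbRanges, TestCase, VertebraModel, VolumeImage
from .projector import FluoroImage

__all__ = [
    "read_volume",
    "write_volume",
    "write_image",
    "read_image",
    "save_case",
    "load_case",
    "results_to_frame",
]


def read_volume(path) -> VolumeImage:
    """Read a NIfTI file or a DICOM series directory into a VolumeImage.

    Axes are taken as stored (assumed to already follow the patient
    convention: x left-right, y caudo-cranial, z fronto-dorsal); voxel
    spacing is preserved exactly.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no volume at {p}")
    if p.is_dir():
        return _read_dicom_series(p)
    img = nib.load(str(p))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise ValueError("expected a 3D volume")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("volume is missing voxel spacing metadata")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return VolumeImage(data, spacing, origin)


def _read_dicom_series(path: Path) -> VolumeImage:
    import pydicom

    files = sorted(path.glob("*.dcm")) or [f for f in sorted(path.iterdir()) if f.is_file()]
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "pixel_array") and hasattr(ds, "ImagePositionPatient"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no readable DICOM slices in {path}")
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    px = slices[0].PixelSpacing
    if len(slices) > 1:
        dz = abs(
            float(slices[1].ImagePositionPatient[2]) - float(slices[0].ImagePositionPatient[2])
        )
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    stack = np.stack([s.pixel_array.astype(np.float32) for s in slices], axis=0)
    # DICOM slices are axial (normal along the body's long axis): slice
    # index -> patient y, pixel rows/cols -> (z, x)
    vol = np.transpose(stack, (2, 0, 1))
    spacing = np.array([float(px[1]), dz, float(px[0])])
    origin = np.array(
        [
            float(slices[0].ImagePositionPatient[0]),
            float(slices[0].ImagePositionPatient[2]),
            float(slices[0].ImagePositionPatient[1]),
        ]
    )
    return VolumeImage(vol, spacing, origin)


def write_volume(volume: VolumeImage, path) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.values.astype(np.float32), affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))


def write_image(img, path, geometry: ProjectionGeometry | None = None, bit16: bool = False) -> None:
    """Write a 2D image as TIFF with a JSON geometry sidecar (same stem)."""
    path = Path(path)
    values = np.asarray(getattr(img, "values", img), dtype=np.float32)
    sidecar = {"provenance": getattr(img, "provenance", "external")}
    g = geometry or getattr(img, "geometry", None)
    if g is not None:
        sidecar["geometry"] = g.to_dict()
    if bit16:
        lo, hi = float(values.min()), float(values.max())
        scale = (hi - lo) / 65535.0 if hi > lo else 1.0
        tifffile.imwrite(str(path), ((values - lo) / scale).round().astype(np.uint16))
        sidecar["intensity"] = {"offset": lo, "scale": scale}
    else:
        tifffile.imwrite(str(path), values)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_image(path) -> FluoroImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no image at {path}")
    values = tifffile.imread(str(path)).astype(np.float64)
    geometry = None
    provenance = "external"
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        provenance = meta.get("provenance", "external")
        if "intensity" in meta:
            values = values * meta["intensity"]["scale"] + meta["intensity"]["offset"]
        if "geometry" in meta:
            geometry = ProjectionGeometry.from_dict(meta["geometry"])
    return FluoroImage(values, geometry=geometry, provenance=provenance)


def _config_to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def _config_from_dict(d: dict) -> CaseConfig:
    d = dict(d)
    d["noise"] = NoiseConfig(**d.get("noise", {}))
    d["perturb"] = PerturbRanges(**d.get("perturb", {}))
    for k in ("shape", "spacing", "angulation_pair", "marker_frame_mm", "detector_shape"):
        if k in d:
            d[k] = tuple(d[k])
    return CaseConfig(**d)


def save_case(tc: TestCase, outdir) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(tc.volume, out / "volume.nii")
    labels = np.zeros(tc.volume.shape, dtype=np.uint8)
    for i, v in enumerate(tc.vertebrae, start=1):
        labels[v.mask] = i
    affine = np.diag(list(tc.volume.spacing) + [1.0])
    affine[:3, 3] = tc.volume.origin
    nib.save(nib.Nifti1Image(labels, affine), str(out / "labels.nii"))
    write_image(tc.fluoro1, out / "fluoro1.tif", tc.geometry1)
    write_image(tc.fluoro2, out / "fluoro2.tif", tc.geometry2)

    rows = []
    for v in tc.vertebrae:
        pose = v.true_pose or RigidPose.identity(v.body_center)
        rows.append(
            {
                "label": v.label,
                **{f"body_{a}": c for a, c in zip("xyz", v.body_center)},
                **{f"pedicle_{a}": c for a, c in zip("xyz", v.left_pedicle)},
                **{f"pose_{k}": val for k, val in zip(("tx", "ty", "tz", "wx", "wy", "wz"), pose.params)},
                **{f"center_{a}": c for a, c in zip("xyz", pose.center)},
            }
        )
    pd.DataFrame(rows).to_csv(out / "landmarks.csv", index=False)
    pd.DataFrame(tc.markers.centers, columns=["x_mm", "y_mm", "z_mm"]).assign(
        radius_mm=tc.markers.radius, attenuation=tc.markers.attenuation
    ).to_csv(out / "markers.csv", index=False)
    manifest = {
        "config": _config_to_dict(tc.config),
        "seed": tc.seed,
        "nominal_rad_deg": tc.rad_deg,
        "realized_rad_deg": tc.realized_rad_deg,
        "files": [
            "volume.nii",
            "labels.nii",
            "fluoro1.tif",
            "fluoro2.tif",
            "landmarks.csv",
            "markers.csv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_case(casedir) -> TestCase:
    d = Path(casedir)
    manifest_path = d / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"{d} is not a case directory (no manifest.json)")
    manifest = json.loads(manifest_path.read_text())
    for f in manifest["files"]:
        if not (d / f).exists():
            raise FileNotFoundError(f"case file missing: {f}")
    config = _config_from_dict(manifest["config"])
    volume = read_volume(d / "volume.nii")
    labels = np.asanyarray(nib.load(str(d / "labels.nii")).dataobj)
    lm = pd.read_csv(d / "landmarks.csv")
    vertebrae = []
    for i, row in enumerate(lm.itertuples(), start=1):
        pose = RigidPose(
            translation=[row.pose_tx, row.pose_ty, row.pose_tz],
            rotation_deg=[row.pose_wx, row.pose_wy, row.pose_wz],
            center=[row.center_x, row.center_y, row.center_z],
        )
        vertebrae.append(
            VertebraModel(
                label=row.label,
                mask=labels == i,
                body_center=[row.body_x, row.body_y, row.body_z],
                left_pedicle=[row.pedicle_x, row.pedicle_y, row.pedicle_z],
                true_pose=pose,
            )
        )
    mk = pd.read_csv(d / "markers.csv")
    markers = MarkerModel(
        mk[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        radius=float(mk["radius_mm"].iloc[0]),
        attenuation=float(mk["attenuation"].iloc[0]),
    )
    f1 = read_image(d / "fluoro1.tif")
    f2 = read_image(d / "fluoro2.tif")
    return TestCase(
        volume=volume,
        vertebrae=vertebrae,
        markers=markers,
        fluoro1=f1,
        fluoro2=f2,
        geometry1=f1.geometry,
        geometry2=f2.geometry,
        config=config,
        seed=int(manifest["seed"]),
    )


def results_to_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "label": r.label,
            "captured": r.captured,
            "converged": r.converged,
            "similarity": r.similarity,
            "evaluations": r.evaluations,
            "note": r.note,
        }
        if r.pose is not None:
            for k, val in zip(("tx", "ty", "tz", "wx", "wy", "wz"), r.pose.params):
                row[f"pose_{k}"] = val
            for a, c in zip("xyz", r.pose.center):
                row[f"center_{a}"] = c
        rows.append(row)
    return pd.DataFrame(rows)
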
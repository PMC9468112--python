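"""Validated run configuration for the command-line pipeline.

A single JSON document drives a whole run: phantom, acquisition factors,
noise, optimizer and seed.  Validation is strict — unknown keys are errors,
marker counts below five and angulations beyond +/-45 deg are rejected —
so factor-space experiments cannot silently drift.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Tuple

from pydantic import BaseModel, ConfigDict, field_validator

from .phantom import CaseConfig, NoiseConfig, PerturbRanges
from .register import RegistrationConfig

__all__ = ["RunConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NoiseSection(_Strict):
    gain: float = 0.003
    gaussian_sd: float = 0.03
    intensity_scale: float = 1.3
    intensity_offset: float = 0.1


class PerturbSection(_Strict):
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 2.0
    wx: float = 5.0
    wy: float = 0.0
    wz: float = 0.0


class OptimizerSection(_Strict):
    stage1_evals: int = 400
    stage2_evals_half: int = 300
    stage2_evals_full: int = 300
    search_bound_mm: float = 10.0
    search_bound_deg: float = 10.0
    use_estimated_relative_pose: bool = True
    exclude_sacral: bool = True


class RunConfig(_Strict):
    """Fully resolved configuration of a simulated registration run."""

    n_vertebrae: int = 5
    centered_label: str = "T7"
    shape: Tuple[int, int, int] = (96, 96, 96)
    spacing: Tuple[float, float, float] = (1.0, 0.67, 1.0)
    angulation_pair: Tuple[float, float] = (-30.0, 30.0)
    angulation_jitter_deg: float = 2.0
    marker_count: int = 8
    detector_skin_mm: float = 200.0
    slice_thickness_mm: Optional[float] = None
    detector_shape: Tuple[int, int] = (256, 256)
    pixel_pitch_mm: float = 1.0
    noise: NoiseSection = NoiseSection()
    perturb: PerturbSection = PerturbSection()
    optimizer: OptimizerSection = OptimizerSection()
    seed: int = 0

    @field_validator("marker_count")
    @classmethod
    def _min_markers(cls, v):
        if v < 5:
            raise ValueError("at least 5 skin markers are required")
        return v

    @field_validator("angulation_pair")
    @classmethod
    def _angulation_range(cls, v):
        for a in v:
            if abs(a) > 45:
                raise ValueError("C-arm angulation limited to +/-45 deg from AP")
        return v

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def case_config(self) -> CaseConfig:
        return CaseConfig(
            n_vertebrae=self.n_vertebrae,
            centered_label=self.centered_label,
            shape=self.shape,
            spacing=self.spacing,
            angulation_pair=self.angulation_pair,
            angulation_jitter_deg=self.angulation_jitter_deg,
            marker_count=self.marker_count,
            detector_skin_mm=self.detector_skin_mm,
            slice_thickness_mm=self.slice_thickness_mm,
            detector_shape=self.detector_shape,
            pixel_pitch_mm=self.pixel_pitch_mm,
            noise=NoiseConfig(**self.noise.model_dump()),
            perturb=PerturbRanges(**self.perturb.model_dump()),
        )

    def registration_config(self) -> RegistrationConfig:
        o = self.optimizer
        return RegistrationConfig(
            stage1_evals=o.stage1_evals,
            stage2_evals_half=o.stage2_evals_half,
            stage2_evals_full=o.stage2_evals_full,
            search_bound_mm=o.search_bound_mm,
            search_bound_deg=o.search_bound_deg,
            use_estimated_relative_pose=o.use_estimated_relative_pose,
            exclude_sacral=o.exclude_sacral,
        )

    def resolved_json(self) -> str:
        return self.model_dump_json(indent=1)

    def digest(self) -> str:
        return hashlib.sha256(self.resolved_json().encode()).hexdigest()[:12]
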
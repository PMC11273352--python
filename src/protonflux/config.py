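"""Validated run configuration for the end-to-end pipelines.

One structured config (YAML or JSON) drives every pipeline stage; CLI flags
override individual fields. Defaults reproduce the reference experiment
analysed throughout this package: bottom compartment acidified from pH 7.3 to
4.1 (61 mM total ionic strength), top at pH 7.3 / 50 mM KCl, a 55 um radius
membrane, a 2.1 / 4 nm hydrophobic-core capacitor, and a -60 mV GHK bias.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .constants import DEFAULT_TEMPERATURE
from .electro import IonConditions
from .shpotential import CapacitorModel, SHCalibration


class ConditionsConfig(BaseModel):
    pH_bottom: float = 4.1
    pH_top: float = 7.3
    cl_bottom_M: float = 0.061
    cl_top_M: float = 0.050
    k_bottom_M: float = 0.050
    k_top_M: float = 0.050
    temperature_K: float = DEFAULT_TEMPERATURE

    def to_conditions(self) -> IonConditions:
        return IonConditions(
            pH_bottom=self.pH_bottom,
            pH_top=self.pH_top,
            cl_bottom=self.cl_bottom_M,
            cl_top=self.cl_top_M,
            k_bottom=self.k_bottom_M,
            k_top=self.k_top_M,
            temperature=self.temperature_K,
        )


class CapacitorConfig(BaseModel):
    dielectric: float = 2.1
    thickness_nm: float = 4.0

    def to_model(self) -> CapacitorModel:
        return CapacitorModel(dielectric=self.dielectric,
                              thickness=self.thickness_nm * 1e-9)


class CalibrationConfig(BaseModel):
    chi3_prime: float = 1.0
    intensity_scale: float = 4.0e4
    chi2_effective: float = 0.0

    def to_calibration(self) -> SHCalibration:
        return SHCalibration(chi3_prime=self.chi3_prime,
                             intensity_scale=self.intensity_scale,
                             chi2_effective=self.chi2_effective)


class SegmentationConfig(BaseModel):
    k_sigma: float = 3.0
    min_area_um2: Optional[float] = None  # default: 4 pixels
    window_frames: int = 20


class StackMetadata(BaseModel):
    """Acquisition metadata accompanying a TIFF stack."""

    frame_period_s: float = 10.0
    pixel_size_um: float = 0.45
    hcl_addition_min: Optional[float] = 10.0


class RunConfig(BaseModel):
    """Everything an end-to-end run needs; validated before any computation."""

    stack_path: Optional[Path] = None
    metadata_path: Optional[Path] = None
    iv_paths: list[Path] = Field(default_factory=list)
    profile_paths: list[Path] = Field(default_factory=list)
    conditions: ConditionsConfig = Field(default_factory=ConditionsConfig)
    capacitor: CapacitorConfig = Field(default_factory=CapacitorConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    metadata: StackMetadata = Field(default_factory=StackMetadata)
    roi_size_um: float = 4.5
    roi_window_frames: int = 60
    membrane_radius_um: float = 55.0
    ghk_bias_V: float = -0.06
    zero_bias_duration_s: float = 3600.0
    conductivity_moles: Optional[float] = None
    seed: int = 0

    @field_validator("roi_size_um", "membrane_radius_um", "zero_bias_duration_s")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be > 0")
        return v

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        return cls.model_validate(raw or {})

    def digest(self) -> str:
        """Stable hash of the config for the provenance block."""
        payload = self.model_dump_json(exclude_none=False)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
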
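"""YAML run configuration with schema validation (pydantic models).

All physical quantities use the mm-N-s-MPa unit system with concentrations
in mEq/ml.  Unknown keys are rejected so typos fail loudly; the JSON schema
is exportable via ``RunConfig.model_json_schema()``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .degeneration import DegenerationConfig
from .fem import LoadingProtocol
from .geometry import CompositionField, CrackSpec, ExplantMesh, build_composition, build_explant_mesh
from .materials import MaterialParams

__all__ = ["RunConfig", "SweepSpec", "load_config", "save_config", "config_hash"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CrackModel(_Model):
    mouth_position: float = Field(gt=0)
    depth: float = Field(gt=0)
    opening_width: float = Field(default=0.05, gt=0)
    inclination: float = 0.0
    profile: Literal["v-notch", "parallel-walled"] = "v-notch"

    def build(self) -> CrackSpec:
        return CrackSpec(**self.model_dump())


class GeometryModel(_Model):
    radius: float = Field(default=1.5, gt=0)
    thickness: float = Field(default=1.0, gt=0)
    target_h: float = Field(default=0.15, gt=0)
    refine_h: Optional[float] = Field(default=None, gt=0)
    growth: float = Field(default=1.4, gt=1)
    refine_lateral: bool = False
    formulation: Literal["plane_strain", "axisymmetric"] = "axisymmetric"
    cracks: list[CrackModel] = Field(default_factory=list)

    def build(self) -> ExplantMesh:
        return build_explant_mesh(
            radius=self.radius, thickness=self.thickness,
            cracks=[c.build() for c in self.cracks],
            target_h=self.target_h, formulation=self.formulation,
            refine_h=self.refine_h, growth=self.growth,
            refine_lateral=self.refine_lateral,
        )


class MaterialModel(_Model):
    E_f: float = Field(default=20.0, gt=0)
    E_nf: float = Field(default=0.16, gt=0)
    nu_nf: float = Field(default=0.42, ge=0, lt=0.5)
    k: float = Field(default=1.3e-3, gt=0)
    C: float = Field(default=3.009, gt=0)
    c_ext: float = Field(default=0.15, gt=0)
    R: float = Field(default=8.3145, gt=0)
    T: float = Field(default=293.0, gt=0)
    phi_int: float = Field(default=1.0, gt=0)
    phi_ext: float = Field(default=1.0, gt=0)
    gamma_int: float = Field(default=1.0, gt=0)
    gamma_ext: float = Field(default=1.0, gt=0)
    a0: float = Field(default=0.0, ge=0)
    kappa: float = Field(default=0.0, ge=0)

    def build(self) -> MaterialParams:
        return MaterialParams(**self.model_dump())


class CompositionModel(_Model):
    arrangement: Literal["arcade", "parallel_to_surface", "perpendicular", "isotropic"] = "arcade"
    fcd_scale: float = Field(default=1.0, ge=0)
    rho_z_scale: float = Field(default=1.0, ge=0)
    rho_z_uniform: bool = False
    n_secondary: int = Field(default=8, ge=1)
    fcd_coeffs: Optional[list[float]] = None  #: degree-6 override, descending powers
    od_profile_csv: Optional[str] = None      #: 2-column CSV replacing the polynomial
    target_mean_fcd: Optional[float] = None   #: required with od_profile_csv

    def build(self, mesh: ExplantMesh) -> CompositionField:
        coeffs = None if self.fcd_coeffs is None else list(self.fcd_coeffs)
        if self.od_profile_csv is not None:
            import pandas as pd

            from .geometry import od_profile_to_fcd

            if self.target_mean_fcd is None:
                raise ValueError("target_mean_fcd is required with od_profile_csv")
            df = pd.read_csv(self.od_profile_csv)
            coeffs = od_profile_to_fcd(
                df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), self.target_mean_fcd
            )
        return build_composition(
            mesh, arrangement=self.arrangement, fcd_coeffs=coeffs,
            fcd_scale=self.fcd_scale, rho_z_scale=self.rho_z_scale,
            rho_z_uniform=self.rho_z_uniform, n_secondary=self.n_secondary,
        )


class ProtocolModel(_Model):
    amplitude: float = Field(default=0.15, ge=0, lt=0.5)
    frequency: float = Field(default=1.0, gt=0)
    pre_strain: float = Field(default=0.0, ge=0)
    n_cycles: int = Field(default=2, ge=1)
    dt: float = Field(default=0.05, gt=0)
    precondition: bool = False
    precondition_time: float = Field(default=300.0, gt=0)

    def build(self) -> LoadingProtocol:
        return LoadingProtocol(waveform="haversine", **self.model_dump())


class DegenerationModel(_Model):
    mechanism: Literal["fluid_velocity", "deviatoric_strain", "max_shear_strain"] = "fluid_velocity"
    eps_dev_thres: float = Field(default=0.20, gt=0)
    eps_shr_thres: float = Field(default=0.50, gt=0)
    v_fl_thres: float = Field(default=0.04, gt=0)
    eps_failure: float = Field(default=1.0, gt=0)
    v_fl_failure: float = Field(default=1.5, gt=0)
    D_r: float = Field(default=0.6, gt=0, le=1)
    n_iterations: int = Field(default=50, ge=1)
    above_failure: Literal["total_loss", "literal_zero"] = "total_loss"

    def build(self) -> DegenerationConfig:
        return DegenerationConfig(**self.model_dump())


class RunConfig(_Model):
    """Top-level run configuration (mm-N-s-MPa units, mEq/ml concentrations)."""

    geometry: GeometryModel = Field(default_factory=GeometryModel)
    material: MaterialModel = Field(default_factory=MaterialModel)
    composition: CompositionModel = Field(default_factory=CompositionModel)
    protocol: ProtocolModel = Field(default_factory=ProtocolModel)
    degeneration: DegenerationModel = Field(default_factory=DegenerationModel)
    output_dir: str = "out"
    seed: int = 0
    stab_alpha: float = Field(default=0.1, ge=0)
    write_fields: bool = True   #: VTK snapshots per iteration
    write_figures: bool = True  #: PNG of the final relative FCD decrease


class SweepSpec(_Model):
    """One-parameter sweep for the parametric analysis."""

    parameter: Literal[
        "arrangement", "initial_FCD_scale", "collagen_density_scale",
        "depth_distribution_variant", "k", "E_f",
    ]
    values: list = Field(min_length=1)
    mechanisms: list[Literal["fluid_velocity", "deviatoric_strain", "max_shear_strain"]] = Field(
        default_factory=lambda: ["fluid_velocity", "deviatoric_strain"]
    )

    def apply(self, base: RunConfig, value) -> RunConfig:
        cfg = base.model_copy(deep=True)
        if self.parameter == "arrangement":
            cfg.composition.arrangement = value
        elif self.parameter == "initial_FCD_scale":
            cfg.composition.fcd_scale = float(value)
        elif self.parameter == "collagen_density_scale":
            cfg.composition.rho_z_scale = float(value)
        elif self.parameter == "depth_distribution_variant":
            cfg.composition.rho_z_uniform = value == "uniform"
        elif self.parameter == "k":
            cfg.material.k = float(value)
        elif self.parameter == "E_f":
            cfg.material.E_f = float(value)
        return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(
        "# cartidegen run configuration (units: mm, N, s, MPa, mEq/ml)\n"
        + yaml.safe_dump(cfg.model_dump(), sort_keys=True)
    )


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the canonical JSON form, for provenance."""
    blob = json.dumps(cfg.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
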
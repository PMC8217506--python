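"""Hierarchical, schema-validated run configuration (YAML).

One document drives every stage of the pipeline; every run writes its
resolved configuration next to its outputs so results are reproducible from
the output directory alone.  Seeds are explicit and mandatory for the
stochastic stages (network generation, image noise, bootstrap).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, ValidationError

from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "dump_config"]


class ImageSection(BaseModel):
    spacing: float = 5.8  # µm; chosen so spacing × coarsen is the element size
    shape: str = "block"
    noise_sd: float = 5.0
    threshold: float = 128.0


class NetworkSection(BaseModel):
    # overrides of the default NetworkCalibration; empty dict = shipped defaults
    calibration: dict = Field(default_factory=dict)


class MeshingSection(BaseModel):
    coarsen: int = 5
    smooth_iterations: int = 2
    smooth_strength: float = 0.3
    beam_max_len: float | None = 58.0  # µm; 2 element lengths


class TissueSection(BaseModel):
    ogden_terms: list = Field(default_factory=lambda: [[1.2, 4.0]])
    prony_terms: list = Field(default_factory=lambda: [[3.0, 0.5], [1.0, 5.0]])
    density: float = 1040.0
    poisson_ratio: float = 0.49998


class VesselSection(BaseModel):
    elastic_modulus: float = 1400.0
    poisson_ratio: float = 0.38
    density: float = 104.0


class MaterialsSection(BaseModel):
    tissue: TissueSection = Field(default_factory=TissueSection)
    vessel: VesselSection = Field(default_factory=VesselSection)


class ScenarioSection(BaseModel):
    # desk-scale indentation of the default 580 µm block; the full-scale
    # 2 mm CCI defaults live in synthetic.make_cci_scenario
    impactor_radius: float = 150.0
    impact_depth: float = 90.0
    impact_velocity: float = 1000.0
    dwell_time: float = 1.0
    retract: bool = True
    total_sim_time: float | None = 2.0
    edge_fillet: float = 80.0  # rounded impactor rim, µm


class SolverSection(BaseModel):
    output_interval: float = 0.01
    safety: float = 0.9
    hourglass_coeff: float = 0.05
    hourglass_stiffness: float = 0.2
    contact_stiffness_scale: float = 0.1
    contact_damping: float = 0.2
    energy_tolerance: float = 0.05
    check_energy: bool = True
    lateral_bc: str = "free"
    total_time: float | None = None


class MappingSection(BaseModel):
    thresholds: list = Field(default_factory=lambda: [150.0, 200.0, 250.0, 300.0])
    neighbourhood_radius: float | None = None  # µm; default one element edge
    slice_axis: int = 1
    slice_coord: float | None = None
    tensile_only: bool = True


class AnalysisSection(BaseModel):
    n_bootstrap: int = 500
    tension_only_correlations: bool = True


class OutputSection(BaseModel):
    directory: str = "runs/demo"
    write_fields: bool = False
    write_image: bool = False


class RunConfig(BaseModel):
    seed: int = 0
    domain_size: list = Field(default_factory=lambda: [580.0, 580.0, 580.0])
    image: ImageSection = Field(default_factory=ImageSection)
    network: NetworkSection = Field(default_factory=NetworkSection)
    meshing: MeshingSection = Field(default_factory=MeshingSection)
    materials: MaterialsSection = Field(default_factory=MaterialsSection)
    scenario: ScenarioSection = Field(default_factory=ScenarioSection)
    solver: SolverSection = Field(default_factory=SolverSection)
    mapping: MappingSection = Field(default_factory=MappingSection)
    analysis: AnalysisSection = Field(default_factory=AnalysisSection)
    output: OutputSection = Field(default_factory=OutputSection)

    model_config = {"extra": "forbid"}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid configuration {path}:\n{exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"unparseable YAML {path}: {exc}") from exc


def dump_config(cfg: RunConfig, path=None) -> str:
    """Serialize a config to YAML (a load → dump → load fixed point)."""
    text = yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
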
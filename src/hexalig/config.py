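"""Validated run configuration (YAML) for the pipeline and CLI.

Concentrations are molar, masses in Da, oligomer orders 1-based.  Unknown
keys are rejected before any computation; the JSON schema is exportable via
``RunConfig.model_json_schema()``.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration failed schema validation."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TopologyBlock(_Block):
    mode: str = "open_chain"  # open_chain | uniform_linear | closed_ring
    max_order: int = 6
    n_override: int | None = None


class BindingBlock(_Block):
    Kd_full: float = 10e-6  # M
    Kd_partial: float = 100e-6  # M
    omega: float = 0.5


class AssemblyBlock(_Block):
    K_step: float = 2e8  # M^-1
    sigma: float = 0.1
    betas: dict[int, float] | None = None  # explicit beta_2..beta_6 override


class SpectrumBlock(_Block):
    protomer_mass: float = 47198.40
    ligand_mass: float = 507.18
    sodium_increment: float = 22.99
    charge_center_coefficient: float = 0.0778
    charge_width: float = 0.9
    peak_sigma_mz: float = 0.15
    sodiation_prob: float = 0.15
    noise_model: str = "gaussian"
    noise_scale: float = 0.002
    mass_offset: float = 0.0
    mz_min: float = 2200.0
    mz_max: float = 7900.0
    mz_step: float = 0.05


class ExtractionBlock(_Block):
    window_halfwidth: float = 1.0
    detection_sigmas: float = 5.0
    baseline: float = 0.0
    charges: dict[int, list[int]] | None = None  # default: envelope mode per j


class FittingBlock(_Block):
    n_starts: int = 8
    n_eff: float = 5000.0
    ligand_mode: str = "speciate"  # speciate | hexamer | total
    fit_oligomers: list[int] = Field(default_factory=lambda: [6])
    n_boot: int = 0
    fix_omega: float | None = None  # log10 omega


class ScenarioBlock(_Block):
    name: str = "fig2_titration"
    protomer_total: float = 10e-6
    atp_grid: list[float] = Field(
        default_factory=lambda: [0.0, 2.5e-6, 5e-6, 10e-6, 20e-6, 40e-6, 100e-6]
    )


class RunConfig(_Block):
    seed: int = 0
    verbosity: int = 1
    scenario: ScenarioBlock = Field(default_factory=ScenarioBlock)
    topology: TopologyBlock = Field(default_factory=TopologyBlock)
    binding: BindingBlock = Field(default_factory=BindingBlock)
    assembly: AssemblyBlock = Field(default_factory=AssemblyBlock)
    spectrum: SpectrumBlock = Field(default_factory=SpectrumBlock)
    extraction: ExtractionBlock = Field(default_factory=ExtractionBlock)
    fitting: FittingBlock = Field(default_factory=FittingBlock)


def load_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; unknown keys raise before computation."""
    if data is None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
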
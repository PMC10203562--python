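"""Campaign configuration (YAML-mirrored, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["CampaignConfig", "ConfigurationError", "load_config"]


class ConfigurationError(ValueError):
    pass


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LibraryBlock(_Block):
    pattern: str = "NNK"
    n_positions: int = Field(4, ge=1)
    cells: float = Field(2.4e8, gt=0)
    efficiency: float = Field(0.017, ge=0.0, le=1.0)
    model: Literal["uniform", "codon_weighted"] = "uniform"
    #: expected pre-selection frequency of the parental amino-acid variant;
    #: the simulator calibrates the oligo-pool bias to hit it
    target_parental_frequency: float = Field(0.013, gt=0.0, lt=1.0)


class GateBlock(_Block):
    display_threshold: float | None = None
    binding_threshold: float | None = None


class SimulationBlock(_Block):
    n_integrants: int = Field(200_000, ge=1)
    #: sorting rounds per gated population
    rounds: dict[str, int] = Field(
        default_factory=lambda: {"best": 4, "affinity": 2, "display": 2}
    )
    gates: dict[str, GateBlock] = Field(
        default_factory=lambda: {
            "best": GateBlock(display_threshold=1.0, binding_threshold=1.0),
            "affinity": GateBlock(binding_threshold=1.0),
            "display": GateBlock(display_threshold=1.0),
        }
    )
    #: MACS pre-enrichment modeled as a permissive display-only gate
    macs_display_threshold: float = -1.0
    n_cells_sorted: int = Field(20_000, ge=1)
    depth: int = Field(50_000, ge=1)
    per_base_error: float = Field(0.001, ge=0.0, lt=0.25)
    cell_noise_sd: float = Field(1.0, ge=0.0)
    seed: int = 0


class EnrichmentBlock(_Block):
    level: Literal["aa", "dna"] = "aa"
    top: int = Field(8, ge=1)
    max_anchor_mismatches: int = Field(1, ge=0)
    pseudocount: float = Field(0.0, ge=0.0)


class AssayBlock(_Block):
    fit_halfwidth_nm: float = Field(10.0, gt=0)
    smooth_window_c: float = Field(3.0, gt=0)
    spectrum_noise_sd: float = Field(0.002, ge=0)
    melt_noise_sd: float = Field(0.002, ge=0)
    elisa_noise_sd: float = Field(0.01, ge=0)


class FlagsBlock(_Block):
    sd_mode: Literal["sample", "population"] = "sample"
    n_reference: int = Field(48, ge=2)
    n_descriptors: int = Field(55, ge=1)


class CampaignConfig(_Block):
    library: LibraryBlock = Field(default_factory=LibraryBlock)
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    enrichment: EnrichmentBlock = Field(default_factory=EnrichmentBlock)
    assays: AssayBlock = Field(default_factory=AssayBlock)
    flags: FlagsBlock = Field(default_factory=FlagsBlock)

    @classmethod
    def from_dict(cls, data: dict) -> "CampaignConfig":
        try:
            return cls.model_validate(data)
        except ValidationError as exc:
            raise ConfigurationError(str(exc)) from exc


def load_config(path: str | Path) -> CampaignConfig:
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    return CampaignConfig.from_dict(data)
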
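"""Validated pipeline configuration (YAML-backed, fully defaulted)."""
from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ParameterError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SynthStage(_Strict):
    """Synthetic demo inputs: two source habitats plus mixed litter sinks."""

    n_taxa: int = Field(150, ge=2)
    samples_per_source: int = Field(6, ge=1)
    n_sinks: int = Field(6, ge=1)
    depth: int = Field(20_000, ge=1)
    dirichlet_concentration: float = Field(0.3, gt=0)
    # phyllosphere, soil, unknown contributions of each synthetic sink
    mixing: list[float] = [0.55, 0.30, 0.15]

    @model_validator(mode="after")
    def _check_mixing(self) -> "SynthStage":
        if len(self.mixing) != 3:
            raise ValueError("mixing needs [phyllosphere, soil, unknown]")
        if any(m < 0 for m in self.mixing) or abs(sum(self.mixing) - 1.0) > 1e-8:
            raise ValueError("mixing must be non-negative and sum to 1")
        return self


class SourcetrackStage(_Strict):
    depth: int | Literal["auto"] = "auto"
    tol: float = Field(1e-6, gt=0)
    max_iter: int = Field(1000, ge=1)


class DiversityStage(_Strict):
    n_perm: int = Field(999, ge=99)
    p_adjust: Literal["BH", "bonferroni", "none"] = "BH"
    shannon_base: Literal["2", "e"] = "2"


class NetworkStage(_Strict):
    top_n: int = Field(400, ge=2)
    method: Literal["spearman", "pearson"] = "spearman"
    r_threshold: float = Field(0.8, gt=0, lt=1)
    p_threshold: float = Field(0.01, gt=0, le=1)
    keystone_quantile: float = Field(0.90, gt=0, lt=1)


class AssemblyStage(_Strict):
    ds: float = Field(0.2, gt=0)
    min_bin_size: int = Field(24, ge=2)
    min_reads: int = Field(0, ge=0)
    n_null: int = Field(999, ge=99)
    nti_cut: float = Field(2.0, gt=0)
    rc_cut: float = Field(0.95, gt=0, le=1)


class StageToggles(_Strict):
    sourcetrack: bool = True
    diversity: bool = True
    network: bool = True
    assembly: bool = True


class InputPaths(_Strict):
    """Optional external inputs; when omitted the synth stage generates them."""

    sinks: Optional[str] = None
    sources: Optional[str] = None
    tree: Optional[str] = None
    metadata: Optional[str] = None


class PipelineConfig(_Strict):
    out_dir: str = "results"
    seed: int = 0
    stages: StageToggles = StageToggles()
    paths: InputPaths = InputPaths()
    synth: SynthStage = SynthStage()
    sourcetrack: SourcetrackStage = SourcetrackStage()
    diversity: DiversityStage = DiversityStage()
    network: NetworkStage = NetworkStage()
    assembly: AssemblyStage = AssemblyStage()

    @model_validator(mode="after")
    def _check_paths(self) -> "PipelineConfig":
        declared = [p for p in (self.paths.sinks, self.paths.sources,
                                self.paths.tree, self.paths.metadata) if p]
        missing = [p for p in declared if not Path(p).exists()]
        if missing:
            raise ValueError(f"configured input path(s) do not exist: {missing}")
        return self


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys and bad values raise."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ParameterError(f"could not parse {path} as YAML: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: config must be a mapping")
    return config_from_dict(data)


def config_from_dict(data: dict) -> PipelineConfig:
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as exc:
        raise ParameterError(str(exc)) from exc
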
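"""Pipeline configuration, loadable from YAML."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["PipelineConfig", "load_config"]


@dataclasses.dataclass
class PipelineConfig:
    samples_path: str = "samples.csv"
    individuals_path: str = "individuals.csv"
    phenology_path: str = "phenology.csv"
    output_dir: str = "output"
    sg_threshold: float = 1.003
    calibration_mode: str = "two_coefficients"  # or "single_regressor"
    fai_tie_rule: str = "strict_greater"  # or "greater_equal"
    basis_dim: int = 10
    glmm_interaction: bool = False
    baseline_class: str = "adult_female"
    make_plots: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.sg_threshold > 1.0:
            raise ConfigurationError("sg_threshold must be > 1.0")
        if self.basis_dim < 3:
            raise ConfigurationError("smooth basis dimension must be >= 3")
        if self.calibration_mode not in ("two_coefficients", "single_regressor"):
            raise ConfigurationError(f"unknown calibration_mode {self.calibration_mode!r}")
        if self.fai_tie_rule not in ("strict_greater", "greater_equal"):
            raise ConfigurationError(f"unknown fai_tie_rule {self.fai_tie_rule!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML mapping."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a YAML mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigurationError(f"{path}: unknown config key(s): {', '.join(unknown)}")
    return PipelineConfig(**raw)
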
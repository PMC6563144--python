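"""YAML configuration with strict validation and materialized defaults.

The config tree mirrors the pipeline stages; unknown keys are rejected
with an itemized error list, and loading an empty document yields the
full default configuration, so a run manifest always records every
effective parameter.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .beadnet import BeadRegressorConfig
from .detect import DetectorConfig
from .siamese import SiameseConfig
from .synth import FlowSequenceSpec, OpticalModel, ZStackSpec
from .train import AugmentationSpec, ConvergenceRule
from .vae import DiscriminatorConfig, VaeArchitecture, VaeConfig


@dataclass(frozen=True)
class AnalysisConfig:
    kmeans_k: int = 2
    kmeans_restarts: int = 10
    fewshot_per_class: int = 10
    svm_kernel: str = "linear"
    svm_c: float = 1.0
    tsne_perplexity: float | None = None
    neighbors_k: int = 4


@dataclass(frozen=True)
class RunConfig:
    """Full end-to-end pipeline configuration."""

    seed: int = 0
    optics: OpticalModel = field(default_factory=OpticalModel)
    flow: FlowSequenceSpec = field(default_factory=FlowSequenceSpec)
    zstack: ZStackSpec = field(default_factory=ZStackSpec)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    bead: BeadRegressorConfig = field(default_factory=BeadRegressorConfig)
    siamese: SiameseConfig = field(default_factory=SiameseConfig)
    vae: VaeConfig = field(default_factory=VaeConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


_NESTED = {
    "optics": OpticalModel, "flow": FlowSequenceSpec, "zstack": ZStackSpec,
    "detector": DetectorConfig, "bead": BeadRegressorConfig,
    "siamese": SiameseConfig, "vae": VaeConfig, "analysis": AnalysisConfig,
    "augmentation": AugmentationSpec, "convergence": ConvergenceRule,
    "arch": VaeArchitecture, "disc": DiscriminatorConfig,
}


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" +
                         "\n".join(f"  - {e}" for e in self.errors))


def _build(cls, data: dict, path: str, errors: list):
    if not isinstance(data, dict):
        errors.append(f"{path}: expected a mapping, got {type(data).__name__}")
        return cls()
    valid = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in valid:
            errors.append(f"{path}.{key}: unknown key")
            continue
        sub = _NESTED.get(key)
        if sub is not None and isinstance(value, dict):
            kwargs[key] = _build(sub, value, f"{path}.{key}", errors)
        elif isinstance(value, list):
            kwargs[key] = tuple(value) if key in ("widths", "frame_size") else value
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{path}: {exc}")
        return cls()


def load_config(path=None, text: str | None = None) -> RunConfig:
    """Load and validate a YAML config; missing keys take defaults,
    unknown keys raise :class:`ConfigError` with an itemized list."""
    if text is None:
        text = Path(path).read_text() if path is not None else ""
    data = yaml.safe_load(text) or {}
    errors: list[str] = []
    cfg = _build(RunConfig, data, "config", errors)
    if errors:
        raise ConfigError(errors)
    return cfg


def _plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    return obj


def dump_config(cfg: RunConfig) -> str:
    """YAML dump with all defaults materialized; load(dump(c)) == c."""
    return yaml.safe_dump(_plain(cfg), sort_keys=False)
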
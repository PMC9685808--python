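"""Run configuration: a flat YAML-serializable record of every knob, with
defaults reproducing the published pipeline settings (augmentation seed 42,
selection fraction 0.7, severity cutoff 0.24 %, 7 samples per label)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .lesionfield import SpeckleSpec
from .synthesis import SynthesisConfig


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips losslessly through YAML."""

    master_seed: int = 0
    out_dir: str = "fluorosynth_out"

    # label source: a directory of label PNGs, or procedural rosettes
    labels_dir: str | None = None
    n_rosettes: int = 10
    canvas_size: int = 128

    # synthesis
    n_per_label: int = 7
    healthy_sampling: str = "per_leaf"
    fixed_day: int | None = None
    delta_distribution: str = "uniform"
    b_floor_frac: float = 0.05
    clip: bool = True

    # lesion speckle
    correlation_length: float = 2.0
    coverage_target: float = 0.05
    lesion_probability: float = 0.8

    # preprocessing
    severity_threshold_pct: float = 0.24
    min_object_px: int = 4
    closing_radius: int = 1

    # augmentation
    augment_fraction: float = 0.7
    augmentation_seed: int = 42

    def validate(self) -> "RunConfig":
        if self.master_seed is None:
            raise ConfigError("master_seed: missing seed")
        if self.n_rosettes < 1 and self.labels_dir is None:
            raise ConfigError("n_rosettes: need >= 1 rosette or a labels_dir")
        if self.n_per_label < 1:
            raise ConfigError("n_per_label: must be >= 1")
        if not 0 <= self.augment_fraction <= 1:
            raise ConfigError("augment_fraction: must lie in [0, 1]")
        if self.healthy_sampling not in ("per_leaf", "per_plant"):
            raise ConfigError("healthy_sampling: must be per_leaf or per_plant")
        if not 0 < self.b_floor_frac < 1:
            raise ConfigError("b_floor_frac: must lie in (0, 1)")
        if self.coverage_target <= 0:
            raise ConfigError("coverage_target: must be positive")
        if not 0 <= self.lesion_probability <= 1:
            raise ConfigError("lesion_probability: must lie in [0, 1]")
        return self

    def synthesis_config(self) -> SynthesisConfig:
        return SynthesisConfig(
            speckle=SpeckleSpec(
                correlation_length=self.correlation_length,
                coverage_target=self.coverage_target,
                lesion_probability=self.lesion_probability,
            ),
            healthy_sampling=self.healthy_sampling,
            fixed_day=self.fixed_day,
            delta_distribution=self.delta_distribution,
            b_floor_frac=self.b_floor_frac,
            clip=self.clip,
            n_per_label=self.n_per_label,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{sorted(unknown)[0]}: unknown config field")
        return cls(**raw).validate()
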
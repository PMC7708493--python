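"""Single YAML pipeline configuration shared by all CLI subcommands."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .model import NetworkSpec, TrainingConfig
from .phantom import IntensityParams, PhantomConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Paths + per-module settings + global seed, YAML round-trippable."""

    output_dir: str = "kidneyvol_out"
    manifest: str | None = None
    checkpoint: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    n_subjects: int = 10
    anomaly_rates: dict = field(default_factory=dict)
    desk_scale: bool = True
    phantom: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    crossval: dict = field(default_factory=lambda: {"k": 3})

    def phantom_config(self, **overrides) -> PhantomConfig:
        kw = dict(self.phantom)
        intensity = kw.pop("intensity_params", None)
        kw.update(overrides)
        for key in ("grid_shape", "voxel_spacing_mm", "motion_offset_mm"):
            if key in kw:
                kw[key] = tuple(kw[key])
        if "kidney_size_range" in kw:
            kw["kidney_size_range"] = tuple(tuple(r) for r in kw["kidney_size_range"])
        if intensity:
            kw["intensity_params"] = IntensityParams(**intensity)
        if self.desk_scale:
            return PhantomConfig.desk_scale(**kw)
        return PhantomConfig(**kw)

    def network_spec(self) -> NetworkSpec:
        kw = dict(self.network)
        if "encoder_widths" in kw:
            kw["encoder_widths"] = tuple(kw["encoder_widths"])
        if self.desk_scale:
            kw.setdefault("width_multiplier", 0.125)
            kw.setdefault("encoder_widths", (64, 128, 256, 512, 512))
        kw.setdefault("seed", self.seed)
        return NetworkSpec(**kw)

    def training_config(self) -> TrainingConfig:
        kw = dict(self.training)
        kw.setdefault("seed", self.seed)
        if self.desk_scale:
            return TrainingConfig.desk_scale(**kw)
        return TrainingConfig(**kw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)
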
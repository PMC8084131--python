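"""Tool configuration: a single YAML file mapping onto the module configs.

Unknown keys are rejected so a typo in a config file fails loudly instead of
silently falling back to a default.  ``dump`` is canonical (sorted keys), so
dump -> load -> dump is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .segment import SegmentationConfig
from .synth import SceneParams

__all__ = ["ClassifierConfig", "ToolConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class ClassifierConfig:
    C: float = 1.0
    max_iterations: int = 500
    train_fraction: float = 0.70
    seed: int = 0
    n_train_per_class: int = 400


@dataclass(frozen=True)
class ToolConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    synth: SceneParams = field(default_factory=SceneParams)
    model_file: str = "model.json"
    output_dir: str = "pollenvia_out"
    log_level: str = "INFO"


def _build(cls, d: dict, context: str):
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {context}: {sorted(unknown)}")
    if cls is SceneParams and "viable_color_mean" in d:
        d = {**d, "viable_color_mean": tuple(d["viable_color_mean"])}
    if cls is SceneParams and "nonviable_color_mean" in d:
        d = {**d, "nonviable_color_mean": tuple(d["nonviable_color_mean"])}
    return cls(**d)


def load_config(path: str | Path | None) -> ToolConfig:
    """Load a YAML config file; None -> all defaults."""
    if path is None:
        return ToolConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {f.name for f in dc_fields(ToolConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    if "segmentation" in raw:
        kwargs["segmentation"] = _build(SegmentationConfig,
                                        raw["segmentation"], "segmentation")
    if "classifier" in raw:
        kwargs["classifier"] = _build(ClassifierConfig, raw["classifier"],
                                      "classifier")
    if "synth" in raw:
        kwargs["synth"] = _build(SceneParams, raw["synth"], "synth")
    for key in ("model_file", "output_dir", "log_level"):
        if key in raw:
            kwargs[key] = raw[key]
    cfg = ToolConfig(**kwargs)
    cfg.segmentation.validate()
    cfg.synth.validate()
    return cfg


def dump_config(cfg: ToolConfig) -> str:
    """Canonical YAML text of a ToolConfig (stable across round-trips)."""
    d = {
        "segmentation": dict(cfg.segmentation.__dict__),
        "classifier": dict(cfg.classifier.__dict__),
        "synth": {**cfg.synth.__dict__,
                  "viable_color_mean": list(cfg.synth.viable_color_mean),
                  "nonviable_color_mean": list(cfg.synth.nonviable_color_mean)},
        "model_file": cfg.model_file,
        "output_dir": cfg.output_dir,
        "log_level": cfg.log_level,
    }
    return yaml.safe_dump(d, sort_keys=True, default_flow_style=False)
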
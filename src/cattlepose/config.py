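"""YAML (de)serialization of model configurations and named presets."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .network import ModelConfig, baseline_config, improved_config

PRESETS = {
    "baseline": baseline_config,
    "improved": improved_config,
}


def config_to_dict(cfg: ModelConfig) -> dict:
    d = asdict(cfg)
    d["simam_stages"] = list(cfg.simam_stages)
    d["neck_channels"] = list(cfg.neck_channels)
    d["repblock_depths"] = list(cfg.repblock_depths)
    return d


def config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    for key in ("simam_stages", "neck_channels", "repblock_depths"):
        if key in d:
            d[key] = tuple(d[key])
    return ModelConfig(**d)


def load_model_config(source: str) -> ModelConfig:
    """Load a preset name ('baseline'/'improved') or a YAML file path."""
    if source in PRESETS:
        return PRESETS[source]()
    raw = yaml.safe_load(Path(source).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"malformed model config: {source}")
    return config_from_dict(raw)


def save_model_config(cfg: ModelConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
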
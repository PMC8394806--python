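"""Run configuration: one YAML file driving synth, augment, model and training.

The file has nested sections mirroring the dataclasses of the corresponding
modules plus a global ``seed`` and ``out_dir``; unknown keys are rejected so
typos fail loudly, and a config round-trips through YAML unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
import yaml

from .dataops import AugmentConfig
from .headnet import ModelConfig
from .synth import SynthConfig
from .training import LossConfig, TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]


def _from_mapping(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in '{section}' section: {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """Global seed, output directory and the per-module config sections."""

    seed: int = 0
    out_dir: str = "runs/default"
    synth: SynthConfig = field(default_factory=SynthConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)

    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {"seed": self.seed, "out_dir": self.out_dir,
                "synth": plain(self.synth), "augment": plain(self.augment),
                "model": plain(self.model), "train": plain(self.train),
                "loss": plain(self.loss)}

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sections = {
            "synth": SynthConfig, "augment": AugmentConfig,
            "model": ModelConfig, "train": TrainConfig, "loss": LossConfig,
        }
        kwargs = {}
        for name, klass in sections.items():
            sec = data.pop(name, {}) or {}
            for key in ("ratio_range_normal", "ratio_range_moderate",
                        "ratio_range_severe", "class_mix"):
                if key in sec and isinstance(sec[key], list):
                    sec[key] = tuple(sec[key])
            kwargs[name] = _from_mapping(klass, sec, name)
        kwargs["seed"] = int(data.pop("seed", 0))
        kwargs["out_dir"] = str(data.pop("out_dir", "runs/default"))
        if data:
            raise ValueError(f"unknown top-level config keys: {sorted(data)}")
        return cls(**kwargs)

    def digest(self) -> str:
        """Stable hash of the full configuration, for run provenance logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
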
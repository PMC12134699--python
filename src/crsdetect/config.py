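"""Run configuration: one place for the pipeline's deployed constants.

Defaults mirror the deployed system: gravity-filter α = 0.8, 200-sample
windows, 450 s notification cooldown, 3 s heartbeat / 6 s timeout,
~20 Hz sampling, CNN trained with lr 0.001 / 100 epochs / batch 32.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .gestures import ProtocolConfig
from .model import ModelConfig, TrainConfig

__all__ = ["RunConfig", "load_run_config", "save_run_config"]


@dataclass(frozen=True)
class RunConfig:
    alpha: float = 0.8
    window_len: int = 200
    cooldown_s: float = 450.0
    heartbeat_interval_s: float = 3.0
    heartbeat_timeout_s: float = 6.0
    sampling_rate_hz: float = 20.0
    seed: int = 0
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.window_len < 1 or self.cooldown_s < 0:
            raise ValueError("window_len must be >= 1 and cooldown_s >= 0")


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    protocol = ProtocolConfig(**raw.pop("protocol", {}))
    mc = raw.pop("model", {})
    if "kernel_sizes" in mc:
        mc["kernel_sizes"] = tuple(tuple(k) for k in mc["kernel_sizes"])
    if "conv_filters" in mc:
        mc["conv_filters"] = tuple(mc["conv_filters"])
    model = ModelConfig(**mc)
    train = TrainConfig(**raw.pop("train", {}))
    return RunConfig(protocol=protocol, model=model, train=train, **raw)


def save_run_config(config: RunConfig, path: str | Path) -> None:
    doc = asdict(config)
    doc["model"]["conv_filters"] = list(doc["model"]["conv_filters"])
    doc["model"]["kernel_sizes"] = [list(k) for k in doc["model"]["kernel_sizes"]]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
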
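"""Run configuration: one YAML-serialisable object tying the stages together."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .alarms import AlarmConfig
from .lion import LionHyper
from .preprocess import StftConfig
from .training import TrainConfig


@dataclasses.dataclass
class RunConfig:
    """Everything a full run needs; see the CLI for the file format."""

    data_dir: str                    # EDF directory (CHB-MIT layout) …
    output_dir: str
    seed: int = 0
    variant: str = "cbam"
    guard_s: float = 14400.0
    stft: StftConfig = dataclasses.field(default_factory=StftConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    alarm: AlarmConfig = dataclasses.field(default_factory=AlarmConfig)
    lion: LionHyper = dataclasses.field(default_factory=LionHyper)

    def __post_init__(self):
        if not Path(self.data_dir).exists():
            raise FileNotFoundError(f"data_dir does not exist: {self.data_dir}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("data_dir", "output_dir"):
            if key not in raw:
                raise KeyError(f"missing required config key: {key!r}")
        kwargs = dict(raw)
        for field, typ in (("stft", StftConfig), ("train", TrainConfig),
                           ("alarm", AlarmConfig), ("lion", LionHyper)):
            if field in kwargs and isinstance(kwargs[field], dict):
                kwargs[field] = typ(**kwargs[field])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stft"]["removed_bands"] = [list(b) for b in self.stft.removed_bands]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)
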
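"""Run configuration: a YAML file with ``generate``/``train``/``provider``
sections, strictly validated (unknown keys are rejected) and re-emittable,
so the resolved configuration logged by a run is itself a valid input.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .tagger import TrainConfig


@dataclass
class GenerateSection:
    n_train: int = 200
    n_test: int = 50
    seed: int = 0
    noise_rate: float = 0.1
    length_range: tuple[int, int] = (20, 160)


@dataclass
class ProviderSection:
    kind: str = "trainable_lookup"
    dim: int = 64

    def __post_init__(self) -> None:
        if self.kind not in ("trainable_lookup", "contextual_adapter"):
            raise ValueError(f"unknown provider kind {self.kind!r}")


@dataclass
class RunConfig:
    generate: GenerateSection = field(default_factory=GenerateSection)
    train: TrainConfig = field(default_factory=TrainConfig)
    provider: ProviderSection = field(default_factory=ProviderSection)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generate"]["length_range"] = list(self.generate.length_range)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True, allow_unicode=True)


def _build(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) in [{section}]: {sorted(unknown)}; expected {sorted(known)}"
        )
    if cls is GenerateSection and "length_range" in data:
        data = dict(data, length_range=tuple(data["length_range"]))
    return cls(**data)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a run configuration; None gives all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a YAML mapping")
    unknown = set(raw) - {"generate", "train", "provider"}
    if unknown:
        raise ValueError(f"unknown top-level section(s): {sorted(unknown)}")
    return RunConfig(
        generate=_build(GenerateSection, raw.get("generate", {}), "generate"),
        train=_build(TrainConfig, raw.get("train", {}), "train"),
        provider=_build(ProviderSection, raw.get("provider", {}), "provider"),
    )
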
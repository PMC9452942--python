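"""Pipeline configuration: strict YAML loading with full round-tripping.

Unknown keys are rejected rather than ignored so a typo in a config file
fails loudly, and any loaded config can be serialized back to disk
byte-for-byte reproducibly (the config hash logged by every command is the
SHA-256 of that canonical serialization).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields

import yaml

from .errors import InvalidParameterError
from .scenes import SceneSpec

__all__ = ["PipelineConfig", "DetectionConfig", "ClassifierConfig", "SynthConfig"]


@dataclass
class SynthConfig:
    n_tiles: int = 4


@dataclass
class NetworkConfig:
    n_candidates: int = 1
    d: float = 4.0


@dataclass
class LossSettings:
    epsilon: str | float = "auto"
    eps_floor: float = 1e-3
    delta: float = 1e-7


@dataclass
class TrainingConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 0.005
    momentum: float = 0.9


@dataclass
class DetectionConfig:
    threshold: float = 0.5
    min_separation: float = 4.0
    match_radius: float = 6.0


@dataclass
class ClassifierConfig:
    radius: float = 30.0
    neighbor_weight: float = 1.0
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 0.01
    momentum: float = 0.9


def _build(cls, mapping, context: str):
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise InvalidParameterError(f"{context}: expected a mapping, got {type(mapping).__name__}")
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise InvalidParameterError(f"{context}: unknown keys {sorted(unknown)}")
    kwargs = dict(mapping)
    for f in fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "out"
    stain_profile: str | None = None  # path to a YAML profile; None = built-in H&E
    scene: SceneSpec = field(default_factory=SceneSpec)
    synth: SynthConfig = field(default_factory=SynthConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    loss: LossSettings = field(default_factory=LossSettings)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    classification: ClassifierConfig = field(default_factory=ClassifierConfig)

    _SECTIONS = {
        "scene": SceneSpec,
        "synth": SynthConfig,
        "network": NetworkConfig,
        "loss": LossSettings,
        "training": TrainingConfig,
        "detection": DetectionConfig,
        "classification": ClassifierConfig,
    }

    @classmethod
    def from_mapping(cls, mapping: dict | None) -> "PipelineConfig":
        mapping = dict(mapping or {})
        unknown = set(mapping) - {f.name for f in fields(cls)}
        if unknown:
            raise InvalidParameterError(f"config: unknown keys {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in mapping:
                section = mapping.pop(name)
                if name == "scene" and isinstance(section, dict) and "appearances" in section:
                    raise InvalidParameterError(
                        "scene.appearances is not configurable from YAML; edit code defaults"
                    )
                kwargs[name] = _build(section_cls, section, name)
        kwargs.update(mapping)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_mapping(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        out = dataclasses.asdict(self)
        out["scene"].pop("appearances", None)
        return plain(out)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.canonical())

    def canonical(self) -> str:
        return yaml.safe_dump(self.to_mapping(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]
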
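"""Experiment configuration: YAML round-trip, defaults and the tiny test-scale preset."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .augment import STRATEGIES, MixupConfig, SDAConfig
from .classify import TrainConfig
from .dreamgan import GanConfig
from .noise import FAMILIES, NoiseSpec
from .phantoms import PhantomSpec


@dataclasses.dataclass
class ExperimentConfig:
    """Everything needed to reproduce one benchmark run from a master seed."""

    phantom: PhantomSpec = dataclasses.field(default_factory=PhantomSpec)
    noise: list[NoiseSpec] = dataclasses.field(
        default_factory=lambda: [NoiseSpec(f) for f in FAMILIES]
    )
    gan: GanConfig = dataclasses.field(default_factory=GanConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    sda: SDAConfig = dataclasses.field(default_factory=SDAConfig)
    mixup: MixupConfig = dataclasses.field(default_factory=MixupConfig)
    strategies: list[str] = dataclasses.field(default_factory=lambda: list(STRATEGIES))
    output_dir: str = "runs"
    master_seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies {sorted(unknown)}; allowed: {STRATEGIES}")

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)) or hasattr(obj, "tolist"):
                return [plain(v) for v in (obj.tolist() if hasattr(obj, "tolist") else obj)]
            if hasattr(obj, "item"):  # numpy scalar
                return obj.item()
            return obj

        return plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        kwargs = {}
        if "phantom" in data:
            kwargs["phantom"] = PhantomSpec(**_tupled(data.pop("phantom"), "lesion_size_range"))
        if "noise" in data:
            kwargs["noise"] = [NoiseSpec(**n) for n in data.pop("noise")]
        if "gan" in data:
            kwargs["gan"] = GanConfig(**_tupled(data.pop("gan"), "betas"))
        if "train" in data:
            kwargs["train"] = TrainConfig(**_tupled(data.pop("train"), "adam_betas"))
        if "sda" in data:
            kwargs["sda"] = SDAConfig(**data.pop("sda"))
        if "mixup" in data:
            kwargs["mixup"] = MixupConfig(**data.pop("mixup"))
        kwargs.update(data)
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _tupled(d: dict, *keys: str) -> dict:
    d = dict(d)
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d


def tiny_config(master_seed: int = 0) -> ExperimentConfig:
    """Desk-scale preset: 32 px phantoms, reduced-depth classifier, short GAN schedule."""
    return ExperimentConfig(
        phantom=PhantomSpec(n_images=130, image_size=32, seed=master_seed),
        gan=GanConfig(image_size=32, width=8, steps=200, batch_size=16, seed=master_seed),
        train=TrainConfig(epochs=10, runs=1, arch_scale="tiny", seed=master_seed),
        strategies=["vanilla", "dreamon"],
        master_seed=master_seed,
    )
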
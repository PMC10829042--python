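"""Run configuration: YAML schema, validation, resolved-copy stamping.

Unknown keys are rejected (typos fail loudly, exit code 2 from the
CLI); every run writes a resolved copy of its configuration next to its
outputs so any artifact can be traced to the exact settings and seed
that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .augment import AugSpec
from .errors import ConfigError
from .model import BackboneSpec, ModelSpec, PyramidSpec
from .seeds import derive_seed
from .synth import SceneSpec
from .train import TrainConfig


@dataclass
class DataSection:
    n_scenes: int = 20
    scene_size: tuple[int, int] = (4096, 4096)
    tile_size: int = 512
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    foreground_fraction_range: tuple[float, float] = (0.30, 0.50)
    copies_per_original: int = 5


@dataclass
class EvalSection:
    split: str = "test"
    batch_size: int = 4


@dataclass
class ProfileSection:
    input_size: tuple[int, int] = (512, 512)


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs/default"
    data: DataSection = field(default_factory=DataSection)
    model: ModelSpec = field(default_factory=ModelSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalSection = field(default_factory=EvalSection)
    profile: ProfileSection = field(default_factory=ProfileSection)

    # -- derived objects -----------------------------------------------------
    def scene_template(self) -> SceneSpec:
        return SceneSpec(size=tuple(self.data.scene_size),
                         foreground_fraction_range=tuple(self.data.foreground_fraction_range))

    def aug_spec(self) -> AugSpec:
        return AugSpec(copies_per_original=self.data.copies_per_original,
                       seed=derive_seed(self.seed, "augment"))

    def as_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.as_dict(), sort_keys=True, default=str)
                              .encode()).hexdigest()[:12]


def _apply(obj, section: dict, path: str) -> None:
    valid = set(obj.__dataclass_fields__)
    for key, value in section.items():
        if key not in valid:
            raise ConfigError(f"unknown config key: {path}{key}")
        current = getattr(obj, key)
        if isinstance(value, list):
            value = tuple(value)
        object.__setattr__(obj, key, type(current)(value) if current is not None
                           and not isinstance(current, (dict,)) else value)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file plus override mapping."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
    if overrides:
        raw = _merge(raw, overrides)
    cfg = RunConfig()
    top_keys = {"seed", "output_dir", "data", "model", "train", "eval", "profile"}
    unknown = set(raw) - top_keys
    if unknown:
        raise ConfigError(f"unknown config key: {sorted(unknown)[0]}")
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "output_dir" in raw:
        cfg.output_dir = str(raw["output_dir"])
    if "data" in raw:
        _apply(cfg.data, dict(raw["data"] or {}), "data.")
    if "model" in raw:
        model_raw = dict(raw["model"] or {})
        known = {"backbone", "pyramid", "head_channels", "num_classes",
                 "input_size", "decoder_dscse", "reduced"}
        unknown = set(model_raw) - known
        if unknown:
            raise ConfigError(f"unknown config key: model.{sorted(unknown)[0]}")
        if model_raw.pop("reduced", False):
            base = ModelSpec.reduced().to_dict()
            base.update(model_raw)
            cfg.model = ModelSpec.from_dict(base)
        else:
            cfg.model = ModelSpec.from_dict({**cfg.model.to_dict(), **model_raw})
        cfg.model.validate()
    if "train" in raw:
        _apply(cfg.train, dict(raw["train"] or {}), "train.")
        cfg.train.validate()
    if "eval" in raw:
        _apply(cfg.eval, dict(raw["eval"] or {}), "eval.")
    if "profile" in raw:
        _apply(cfg.profile, dict(raw["profile"] or {}), "profile.")
    return cfg


def _merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def save_resolved(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Write the resolved config (with its hash) next to the run outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "resolved_config.yaml"
    payload = cfg.as_dict()
    payload["config_hash"] = cfg.config_hash()
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return path
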
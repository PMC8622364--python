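"""Run configuration: aggregation, flat key=value files, overrides, logging.

A RunConfig bundles the training, backbone, synthetic-data, and
evaluation settings behind one key namespace.  Defaults are the
full-scale study settings (tile 512 / stride 256, k=16, N=256, batch 32,
lr 0.001 with 0.95 decay every 2 epochs, Adam betas 0.9/0.999, stop
patience 10, bootstrap 1000, threshold 0.5).  Precedence: CLI overrides
> config file > defaults.  Every resolved run writes a JSON snapshot of
itself next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path

from .errors import ConfigurationError
from .model import BackboneConfig
from .synthetic import SynthConfig
from .training import TrainingConfig


@dataclass
class EvalSettings:
    threshold: float = 0.5
    bootstrap_iterations: int = 1000


@dataclass
class RunConfig:
    training: TrainingConfig = field(default_factory=TrainingConfig)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    evaluation: EvalSettings = field(default_factory=EvalSettings)
    log_level: str = "INFO"
    seed: int = 0

    _SECTIONS = ("training", "backbone", "synth", "evaluation")

    def _owner(self, key: str):
        for section in self._SECTIONS:
            sub = getattr(self, section)
            if key in {f.name for f in fields(sub)}:
                return sub
        return None

    def apply(self, overrides: dict[str, str]) -> "RunConfig":
        """Apply string key=value overrides with type coercion; unknown keys error."""
        unknown = []
        for key, raw in overrides.items():
            if key == "seed":
                self.set_seed(_coerce(raw, int, key))
                continue
            if key in ("log_level",):
                self.log_level = str(raw)
                continue
            owner = self._owner(key)
            if owner is None:
                unknown.append(key)
                continue
            ftype = {f.name: f.type for f in fields(owner)}[key]
            setattr(owner, key, _coerce(raw, ftype, key))
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        # re-run invariant checks
        self.training = TrainingConfig(**dataclasses.asdict(self.training))
        self.synth = SynthConfig(**dataclasses.asdict(self.synth))
        return self

    def set_seed(self, seed: int) -> None:
        """The master seed drives every stage's randomness."""
        self.seed = seed
        self.training.seed = seed
        self.backbone.seed = seed
        self.synth.seed = seed

    def snapshot(self) -> dict:
        return {
            "training": dataclasses.asdict(self.training),
            "backbone": dataclasses.asdict(self.backbone),
            "synth": dataclasses.asdict(self.synth),
            "evaluation": dataclasses.asdict(self.evaluation),
            "log_level": self.log_level,
            "seed": self.seed,
        }

    def write_snapshot(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.snapshot(), indent=2, default=str))


def _coerce(raw, ftype, key: str):
    """Coerce a string override to a dataclass field type."""
    if not isinstance(raw, str):
        return raw
    t = str(ftype)
    try:
        if "tuple" in t:
            parts = [p.strip() for p in raw.replace("(", "").replace(")", "").split(",")]
            conv = float if "float" in t else int
            return tuple(conv(p) for p in parts)
        if "bool" in t:
            return raw.strip().lower() in ("1", "true", "yes")
        if "int" in t:
            if raw.strip().lower() in ("none", ""):
                return None
            return int(raw)
        if "float" in t:
            return float(raw)
    except ValueError as exc:
        raise ConfigurationError(f"cannot parse {key}={raw!r}: {exc}") from exc
    if raw.strip().lower() == "none":
        return None
    return raw


def parse_kv_file(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{i}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        out[key] = value
    return out


def load_run_config(config_file: str | Path | None = None,
                    overrides: dict[str, str] | None = None,
                    seed: int | None = None) -> RunConfig:
    cfg = RunConfig()
    if seed is not None:
        cfg.set_seed(seed)
    if config_file is not None:
        cfg.apply(parse_kv_file(config_file))
    if overrides:
        cfg.apply(overrides)
    return cfg


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=getattr(logging, level.upper(), logging.INFO),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s",
                        handlers=handlers, force=True)
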
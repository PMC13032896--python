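"""Run configuration: validation, normalisation, hashing, and the
stage-slot arithmetic for full learning-curve runs."""

from __future__ import annotations

import difflib
import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError

__all__ = ["RunConfig", "validate_config", "config_hash", "count_model_slots"]


class DesignSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = 1000
    k: int = 4
    outer_loops: int = 20
    inner_loops: int | None = None
    initial_threshold_quantile: float = 0.3
    threshold_decay: float = 0.85


class SimulateSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    preset: Literal["default", "null", "noisy"] = "default"
    noise_sd: float | None = None


class TrainSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    backends: list[str] = Field(default_factory=lambda: ["random_forest"])
    n_search: int = 5
    cv_folds: int = 5
    train_fraction: float = 0.8
    fixed_test_size: int = 2000
    property: Literal["ap", "logp", "pi"] = "ap"


class AttributeSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    shap_rows: int = 200
    n_search: int = 0


class RunConfig(BaseModel):
    """Validated end-to-end run configuration with defaults filled in."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "runs/demo"
    design: DesignSection = Field(default_factory=DesignSection)
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    train: TrainSection = Field(default_factory=TrainSection)
    attribute: AttributeSection = Field(default_factory=AttributeSection)

    def normalized(self) -> dict:
        return json.loads(self.model_dump_json())


_KNOWN_KEYS = [
    "seed", "out_dir", "design", "simulate", "train", "attribute",
    "n", "k", "outer_loops", "inner_loops", "initial_threshold_quantile",
    "threshold_decay", "preset", "noise_sd", "backends", "n_search",
    "cv_folds", "train_fraction", "fixed_test_size", "property",
    "enabled", "shap_rows",
]


def validate_config(path: str | Path | dict) -> RunConfig:
    """Load and validate a YAML run config, reporting all errors at once.

    Unknown keys are named together with the nearest valid key; domain
    errors (e.g. a design size not divisible by 20) are surfaced here
    rather than mid-run.
    """
    if isinstance(path, dict):
        data = path
    else:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file {p} does not exist")
        data = yaml.safe_load(p.read_text()) or {}
    errors: list[str] = []
    cfg: RunConfig | None = None
    try:
        cfg = RunConfig.model_validate(data)
    except ValidationError as exc:
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"])
            msg = err["msg"]
            if err["type"] == "extra_forbidden":
                key = str(err["loc"][-1])
                near = difflib.get_close_matches(key, _KNOWN_KEYS, n=1)
                hint = f" (did you mean {near[0]!r}?)" if near else ""
                errors.append(f"unknown key {loc!r}{hint}")
            else:
                errors.append(f"{loc}: {msg}")
    if cfg is not None:
        if cfg.design.n % 20:
            errors.append(
                f"design.n={cfg.design.n} is not divisible by the 20 residue levels"
            )
        if cfg.design.n and 20**cfg.design.k - cfg.design.n < cfg.train.fixed_test_size:
            errors.append(
                "design.n leaves too few sequences for the fixed test set"
            )
    if errors:
        raise ConfigError("; ".join(errors))
    assert cfg is not None
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable sha256 over the normalised config (key order independent)."""
    canon = json.dumps(cfg.normalized(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def count_model_slots(n_sizes: int = 31, n_properties: int = 3, n_backends: int = 3) -> int:
    """Number of model artifacts in a full learning-curve run (31*3*3=279)."""
    return n_sizes * n_properties * n_backends
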
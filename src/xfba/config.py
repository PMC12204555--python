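"""Run configuration loading for the command-line interface."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .io import read_model_table
from .model import MetabolicModel

__all__ = ["RunConfig", "ConfigError", "load_config"]

_KNOWN_KEYS = {
    "model", "models", "scenario", "pins", "grid", "coupling", "abundances",
    "shared", "outdir", "seed", "log_level", "objective", "args",
}
_COUPLING_KEYS = {
    "r", "alpha", "mw_phb", "p_base", "growth_id", "diff_id", "phb_flux_id",
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    scenario: str
    models: dict[str, Path] = field(default_factory=dict)  # tag -> path
    pins: dict[str, float] = field(default_factory=dict)
    grid: list[float] = field(default_factory=list)
    coupling: dict[str, float | str] = field(default_factory=dict)
    abundances: dict[str, float] = field(default_factory=dict)
    shared: list[str] | str = "all-extracellular"
    outdir: Path = Path("results")
    seed: int = 0
    log_level: str = "INFO"
    objective: str | None = None
    args: dict = field(default_factory=dict)
    config_hash: str = ""
    loaded: dict[str, MetabolicModel] = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected by name; referenced model files must exist and
    every pin must name a reaction present in one of the loaded models.  A
    SHA-256 hash of the file is recorded for provenance.
    """
    path = Path(path)
    raw = path.read_bytes()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = sorted(set(data) - _KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {unknown}")
    if "scenario" not in data:
        raise ConfigError(f"{path}: 'scenario' is required")

    models: dict[str, Path] = {}
    if "model" in data:
        models["model"] = Path(data["model"])
    for tag, p in (data.get("models") or {}).items():
        models[tag] = Path(p)
    for tag, p in models.items():
        if not p.is_absolute():
            models[tag] = path.parent / p
        if not models[tag].exists():
            raise ConfigError(f"{path}: model file {models[tag]} does not exist")

    coupling = data.get("coupling") or {}
    bad = sorted(set(coupling) - _COUPLING_KEYS)
    if bad:
        raise ConfigError(f"{path}: unknown coupling key(s) {bad}")

    grid = data.get("grid") or []
    if not all(isinstance(v, (int, float)) for v in grid):
        raise ConfigError(f"{path}: grid must be a finite list of numbers")

    cfg = RunConfig(
        scenario=str(data["scenario"]),
        models=models,
        pins={str(k): float(v) for k, v in (data.get("pins") or {}).items()},
        grid=[float(v) for v in grid],
        coupling=coupling,
        abundances={str(k): float(v)
                    for k, v in (data.get("abundances") or {}).items()},
        shared=data.get("shared", "all-extracellular"),
        outdir=Path(data.get("outdir", "results")),
        seed=int(data.get("seed", 0)),
        log_level=str(data.get("log_level", "INFO")),
        objective=data.get("objective"),
        args=data.get("args") or {},
        config_hash=hashlib.sha256(raw).hexdigest(),
    )
    cfg.loaded = {tag: read_model_table(p) for tag, p in cfg.models.items()}
    known_reactions = {
        rid for m in cfg.loaded.values() for rid in m.reactions
    }
    # pins with a bracketed tag address community-level reactions that only
    # exist after the merge; those are checked when the community is built
    missing = sorted(
        p for p in cfg.pins if p not in known_reactions and "[" not in p
    )
    if missing:
        raise ConfigError(
            f"{path}: pinned reaction(s) {missing} not present in the loaded "
            f"model(s)"
        )
    return cfg
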
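"""Run configuration: YAML loading, validation and seed splitting.

A run is described by one YAML document with optional blocks ``space``,
``oracle``, ``al``, ``region`` plus a global ``seed`` and an ``out_dir``.
Unknown keys anywhere in the document are rejected by name; missing keys take
deterministic defaults, so an empty file is a valid full configuration. The
resolved configuration is echoed back into every run directory.

A single global seed is expanded into per-component seeds through fixed
offsets (see :mod:`probitab.active_learning`) so that the validation design,
candidate pools and hyperparameter tuner stay independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .active_learning import ALConfig
from .design import DesignSpace
from .oracle import OracleParams, default_params

__all__ = ["RunConfig", "RegionConfig", "ConfigError", "load_config",
           "dump_config"]


class ConfigError(ValueError):
    """Invalid run configuration (unknown key, bad type or bad bounds)."""


@dataclass(frozen=True)
class RegionConfig:
    """Near-optimal region search settings."""

    n_candidates: int = 5000
    frac: float = 0.99
    alpha: float | None = None   # None: smallest single-component radius

    def __post_init__(self):
        if self.n_candidates < 4:
            raise ConfigError("region.n_candidates must be >= 4")
        if not 0.0 < self.frac <= 1.0:
            raise ConfigError("region.frac must lie in (0, 1]")
        if self.alpha is not None and self.alpha <= 0:
            raise ConfigError("region.alpha must be positive or null")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    space: DesignSpace = field(default_factory=DesignSpace)
    oracle: OracleParams = field(default_factory=lambda: default_params(True))
    al: ALConfig = field(default_factory=ALConfig)
    region: RegionConfig = field(default_factory=RegionConfig)
    seed: int = 0
    out_dir: str = "runs"


_SPACE_KEYS = {"speed", "pre", "main", "pre_max"}
_REGION_KEYS = {"n_candidates", "frac", "alpha"}
_AL_KEYS = {"n_init", "n_iter", "pool_size", "n_val", "retune_every",
            "tune_budget"}
_TOP_KEYS = {"space", "oracle", "al", "region", "seed", "out_dir"}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _pair(value, name: str) -> tuple[float, float]:
    if (not isinstance(value, (list, tuple)) or len(value) != 2
            or not all(isinstance(v, (int, float)) for v in value)):
        raise ConfigError(f"{name} must be a [lo, hi] pair of numbers")
    lo, hi = float(value[0]), float(value[1])
    if lo >= hi:
        raise ConfigError(f"{name}: lower bound {lo} must be < upper {hi}")
    return lo, hi


def _load_space(block: dict) -> DesignSpace:
    _check_keys(block, _SPACE_KEYS, "space")
    if "pre" in block and "pre_max" in block:
        raise ConfigError("space: give either pre or pre_max, not both")
    kw = {}
    for axis in ("speed", "pre", "main"):
        if axis in block:
            kw[f"{axis}_lo"], kw[f"{axis}_hi"] = _pair(block[axis],
                                                       f"space.{axis}")
    if "pre_max" in block:
        v = block["pre_max"]
        if v == "main":
            v = kw.get("main_hi", DesignSpace().main_hi)
        if not isinstance(v, (int, float)):
            raise ConfigError('space.pre_max must be a number or "main"')
        kw["pre_lo"], kw["pre_hi"] = 0.0, float(v)
    try:
        return DesignSpace(**kw)
    except ValueError as exc:
        raise ConfigError(f"space: {exc}") from exc


def _load_oracle(block) -> OracleParams:
    if isinstance(block, str):                      # path to calibrated JSON
        from .oracle import load_params
        path = Path(block)
        if not path.exists():
            raise ConfigError(f"oracle parameter file not found: {block}")
        return load_params(path)
    if isinstance(block, dict):
        base = default_params(calibrated=True).to_dict()
        for key, val in block.items():
            if key in ("material", "tolerance"):
                if not isinstance(val, dict):
                    raise ConfigError(f"oracle.{key} must be a mapping")
                unknown = set(val) - set(base[key])
                if unknown:
                    raise ConfigError(
                        f"unknown key(s) in oracle.{key}: {sorted(unknown)}")
                base[key].update(val)
            elif key in base:
                base[key] = val
            else:
                raise ConfigError(f"unknown key(s) in oracle: [{key!r}]")
        try:
            return OracleParams.from_dict(base)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"oracle: {exc}") from exc
    raise ConfigError("oracle must be a mapping or a path string")


def load_config(path, seed: int | None = None) -> RunConfig:
    """Load, validate and resolve a YAML run configuration.

    ``seed`` overrides the file's global seed (CLI ``--seed``). An empty or
    missing-block document resolves to all defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) if path is not None else None
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "configuration root")

    space = _load_space(raw.get("space", {}) or {})
    oracle = _load_oracle(raw.get("oracle", {}) or {})

    al_block = raw.get("al", {}) or {}
    _check_keys(al_block, _AL_KEYS, "al")
    region_block = raw.get("region", {}) or {}
    _check_keys(region_block, _REGION_KEYS, "region")

    cfg_seed = raw.get("seed", 0)
    if not isinstance(cfg_seed, int):
        raise ConfigError("seed must be an integer")
    if seed is not None:
        cfg_seed = int(seed)

    try:
        al = ALConfig(seed=cfg_seed, **al_block)
        region = RegionConfig(**region_block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    out_dir = raw.get("out_dir", "runs")
    if not isinstance(out_dir, str):
        raise ConfigError("out_dir must be a string")
    return RunConfig(space=space, oracle=oracle, al=al, region=region,
                     seed=cfg_seed, out_dir=out_dir)


def dump_config(cfg: RunConfig) -> str:
    """Resolved configuration as a YAML document (echoed into run dirs)."""
    doc = {
        "space": {"speed": [cfg.space.speed_lo, cfg.space.speed_hi],
                  "pre": [cfg.space.pre_lo, cfg.space.pre_hi],
                  "main": [cfg.space.main_lo, cfg.space.main_hi]},
        "oracle": cfg.oracle.to_dict(),
        "al": {"n_init": cfg.al.n_init, "n_iter": cfg.al.n_iter,
               "pool_size": cfg.al.pool_size, "n_val": cfg.al.n_val,
               "retune_every": cfg.al.retune_every,
               "tune_budget": cfg.al.tune_budget},
        "region": {"n_candidates": cfg.region.n_candidates,
                   "frac": cfg.region.frac, "alpha": cfg.region.alpha},
        "seed": cfg.seed,
        "out_dir": cfg.out_dir,
    }
    return yaml.safe_dump(doc, sort_keys=False)
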
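"""Run configuration (YAML) and stage manifests."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import yaml

__all__ = ["ConfigError", "DataError", "load_config", "validate_config",
           "config_hash", "write_manifest", "read_manifest", "stage_cached"]

KNOWN_TOP_KEYS = {"seed", "outdir", "plot", "synthetic", "mode", "grid",
                  "species", "period", "randomize", "allometry", "community"}


class ConfigError(Exception):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(Exception):
    """Missing or invalid input data / upstream artifacts (CLI exit code 3)."""


def load_config(path) -> dict:
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        cfg = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"config is not valid YAML: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    errors = validate_config(cfg)
    if errors:
        raise ConfigError("invalid config:\n  - " + "\n  - ".join(errors))
    return cfg


def validate_config(cfg: dict) -> list[str]:
    """Exhaustive validation; returns all problems, not just the first."""
    errors = []
    for key in cfg:
        if key not in KNOWN_TOP_KEYS:
            errors.append(f"unknown key {key!r}")
    if "outdir" not in cfg:
        errors.append("missing required key 'outdir'")
    mode = cfg.get("mode", {})
    for key, allowed in (("fill", {"equal", "larsm"}),
                         ("adjust", {"removal", "relocation"}),
                         ("position", {"stem", "crown"}),
                         ("decay", {"none", "linear", "squared"})):
        v = mode.get(key)
        if v is not None and v not in allowed:
            errors.append(f"mode.{key} must be one of {sorted(allowed)}")
    grid = cfg.get("grid", {})
    radii = grid.get("radii")
    if radii is not None and not (radii == "full" or (
            isinstance(radii, list) and all(isinstance(r, (int, float)) and r > 0
                                            for r in radii))):
        errors.append("grid.radii must be 'full' or a list of positive numbers")
    dd = grid.get("dd_levels")
    if dd is not None and not (dd == "full" or (
            isinstance(dd, list) and all(isinstance(x, (int, float)) and x >= 0
                                         for x in dd))):
        errors.append("grid.dd_levels must be 'full' or a list of >= 0 numbers")
    if "period" in cfg and (not isinstance(cfg["period"], int)
                            or cfg["period"] < 1):
        errors.append("period must be a positive integer")
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        errors.append("seed must be an integer")
    return errors


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _manifest_path(outdir: Path, stage: str) -> Path:
    return Path(outdir) / f"{stage}.manifest.json"


def write_manifest(outdir, stage: str, cfg: dict, seed: int,
                   outputs: list[str], inputs: dict | None = None) -> None:
    from . import __version__
    m = {"stage": stage, "config_hash": config_hash(cfg), "seed": seed,
         "outputs": outputs, "inputs": inputs or {},
         "version": __version__, "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    _manifest_path(outdir, stage).write_text(json.dumps(m, indent=1))


def read_manifest(outdir, stage: str) -> dict | None:
    p = _manifest_path(outdir, stage)
    return json.loads(p.read_text()) if p.exists() else None


def stage_cached(outdir, stage: str, cfg: dict, seed: int) -> bool:
    """True when the stage already ran with this config hash and seed and
    all its outputs still exist."""
    m = read_manifest(outdir, stage)
    if m is None:
        return False
    if m.get("config_hash") != config_hash(cfg) or m.get("seed") != seed:
        return False
    return all((Path(outdir) / o).exists() for o in m.get("outputs", []))
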
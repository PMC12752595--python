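"""Run configuration, seed fan-out and provenance records.

A single global seed is fanned out into named per-component streams so that
fixture generation, forward noising, training and sampling each consume
independent, reproducible randomness.  Every CLI run writes a provenance
JSON (resolved config + seed + package version) next to its outputs; any
output is regenerable from that record.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml


def child_seed(global_seed: int, name: str) -> int:
    """Deterministic named sub-seed (stable across platforms, < 2**31)."""
    tag = zlib.crc32(name.encode())
    return int(np.random.SeedSequence([int(global_seed), tag]).generate_state(1)[0] % (2**31))


def child_rng(global_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(global_seed, name))


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending key."""


def load_config(path: str | Path, schema: dict[str, type] | None = None) -> dict:
    """Load a YAML config and (optionally) validate keys against a schema
    mapping key -> type; unknown or mistyped keys raise ConfigError."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("top-level config must be a mapping")
    if schema is not None:
        for key, val in cfg.items():
            if key not in schema:
                raise ConfigError(f"unknown config key: {key!r}")
            want = schema[key]
            if want is float and isinstance(val, int):
                val = float(val)
            if not isinstance(val, want):
                raise ConfigError(
                    f"config key {key!r}: expected {want.__name__}, got {type(val).__name__}")
    return cfg


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_provenance(path: str | Path, command: str, config: dict, seed: int) -> None:
    from . import __version__

    record = {
        "command": command,
        "config": _jsonable(config),
        "seed": int(seed),
        "package_version": __version__,
        "written_at": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
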
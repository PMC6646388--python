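"""YAML configuration: one file drives digestion, ion math, refinement,
validation and simulation settings. Flags given on the command line win
over file values; the fully resolved configuration is hashed and stamped
into every output header for provenance."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import yaml

from .digestion import DigestParams
from .ion_math import CEParams, MassConstants
from .simulate import SimConfig
from .validation import Thresholds

DEFAULTS: dict[str, dict[str, Any]] = {
    "digest": {},
    "mass": {},        # fixed_mods override, e.g. {fixed_mods: {}} to disable CAM-C
    "ce": {},          # per_charge: [[2, 0.034, 3.314], ...]
    "refine": {"k": 5, "r_threshold": 0.9, "min_total_auc": 0.0},
    "validation": {},
    "simulate": {},
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge defaults <- YAML file <- explicit overrides (flags win)."""
    merged = {k: dict(v) for k, v in DEFAULTS.items()}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a mapping")
        for section, values in data.items():
            if section not in merged:
                raise ValueError(f"unknown config section {section!r}")
            merged[section].update(values or {})
    for section, values in (overrides or {}).items():
        merged.setdefault(section, {}).update(values)
    return merged


def digest_params(config: dict) -> DigestParams:
    kw = dict(config.get("digest", {}))
    if "exclude_residues" in kw:
        kw["exclude_residues"] = frozenset(kw["exclude_residues"])
    return DigestParams(**kw)


def mass_constants(config: dict) -> MassConstants:
    return MassConstants(**config.get("mass", {}))


def ce_params(config: dict) -> CEParams:
    kw = dict(config.get("ce", {}))
    if "per_charge" in kw:
        kw["per_charge"] = tuple(tuple(row) for row in kw["per_charge"])
    return CEParams(**kw)


def thresholds(config: dict) -> Thresholds:
    return Thresholds(**config.get("validation", {}))


def sim_config(config: dict, seed: int | None = None) -> SimConfig:
    kw = dict(config.get("simulate", {}))
    if seed is not None:
        kw["seed"] = seed
    if "amplitude_range" in kw:
        kw["amplitude_range"] = tuple(kw["amplitude_range"])
    return SimConfig(**kw)


def config_hash(config: dict) -> str:
    """Stable short hash of the resolved configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(config: dict, seed: int | None = None) -> list[str]:
    lines = [f"mrmpanel config_hash={config_hash(config)}"]
    if seed is not None:
        lines.append(f"seed={seed}")
    return lines
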
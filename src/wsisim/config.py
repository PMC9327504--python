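"""YAML run-configuration: sections ``scanner``, ``policy``, ``quality``, ``fleet``.

Example::

    scanner: {name: S1, time_model: poisson, mean_scan_s: 60, load_s: 10, capacity: 360}
    quality: {sigma: 0.15, threshold: 0.1, bad_cutoff: 0.05}
    policy:  {auto_rescan_rate: 0.05, rescan_multiplier: 2.0}
    fleet:
      daily_load: 400
      scanners:
        - {name: S1, capacity: 1000}
        - {name: S2, capacity: 100}

Command-line flags override config values; every key has the dataclass
default when omitted.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Any

import yaml

from .quality_model import QualityModel
from .scan_model import ScannerProfile
from .workflow import QCPolicy

__all__ = ["RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _build(cls, section: dict[str, Any] | None, name: str):
    section = dict(section or {})
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in config section {name!r}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config section {name!r}: {exc}") from exc


@dataclasses.dataclass
class RunConfig:
    scanner: ScannerProfile
    policy: QCPolicy
    fleet_scanners: list[ScannerProfile]
    daily_load: int | None = None


def load_config(path: str | os.PathLike | None) -> RunConfig:
    """Parse a YAML config file; a missing path yields all defaults."""
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
    unknown = set(raw) - {"scanner", "policy", "quality", "fleet"}
    if unknown:
        raise ConfigError(f"unknown top-level config section(s) {sorted(unknown)}")

    scanner = _build(ScannerProfile, raw.get("scanner"), "scanner")
    quality = _build(QualityModel, raw.get("quality"), "quality")
    policy_section = dict(raw.get("policy") or {})
    policy_section["quality"] = quality
    policy = _build(QCPolicy, policy_section, "policy")

    fleet_raw = dict(raw.get("fleet") or {})
    daily_load = fleet_raw.pop("daily_load", None)
    scanners_raw = fleet_raw.pop("scanners", None)
    if fleet_raw:
        raise ConfigError(f"unknown key(s) {sorted(fleet_raw)} in config section 'fleet'")
    fleet_scanners = (
        [_build(ScannerProfile, s, "fleet.scanners") for s in scanners_raw]
        if scanners_raw
        else [scanner]
    )
    return RunConfig(
        scanner=scanner,
        policy=policy,
        fleet_scanners=fleet_scanners,
        daily_load=daily_load,
    )
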
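"""Run configuration: weights, thresholds, detector parameters, policies.

Configuration merges three layers — package defaults, an optional
YAML-style file, and explicit overrides — and records the provenance of
every value.  Unknown sections or keys are rejected.  File layout::

    weights:
      sp_sec: 1.0
      builtin_sp_sec: 2.0
    thresholds:
      extra: 2
    detectors:
      tm_threshold: 1.6
    builtin_detectors: missing   # missing | always | never
    unknown_policy: negative     # negative | exclude
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .detectors import DetectorConfig
from .engine import Thresholds, Weights
from .errors import ConfigError

BUILTIN_MODES = ("missing", "always", "never")
UNKNOWN_POLICIES = ("negative", "exclude")

_SECTIONS = {
    "weights": Weights,
    "thresholds": Thresholds,
    "detectors": DetectorConfig,
}
_SCALARS = {
    "builtin_detectors": BUILTIN_MODES,
    "unknown_policy": UNKNOWN_POLICIES,
}


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of one run, with per-value provenance."""

    weights: Weights = field(default_factory=Weights)
    thresholds: Thresholds = field(default_factory=Thresholds)
    detectors: DetectorConfig = field(default_factory=DetectorConfig)
    builtin_detectors: str = "missing"
    unknown_policy: str = "negative"
    provenance: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.builtin_detectors not in BUILTIN_MODES:
            raise ConfigError(
                f"builtin_detectors must be one of {BUILTIN_MODES}, "
                f"got {self.builtin_detectors!r}"
            )
        if self.unknown_policy not in UNKNOWN_POLICIES:
            raise ConfigError(
                f"unknown_policy must be one of {UNKNOWN_POLICIES}, "
                f"got {self.unknown_policy!r}"
            )

    def effective(self) -> dict[str, Any]:
        """Nested plain-dict view of every effective value."""
        out: dict[str, Any] = {}
        for section, cls in _SECTIONS.items():
            obj = getattr(self, section)
            out[section] = {f.name: getattr(obj, f.name) for f in fields(cls)}
        out["builtin_detectors"] = self.builtin_detectors
        out["unknown_policy"] = self.unknown_policy
        return out


def _merge_section(cls, base, updates: Mapping, origin: str, provenance, section):
    valid = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in updates.items():
        if key not in valid:
            raise ConfigError(
                f"unknown key {section}.{key!r}; valid keys: {sorted(valid)}"
            )
        if not isinstance(value, (int, float)):
            raise ConfigError(f"{section}.{key} must be numeric, got {value!r}")
        kwargs[key] = type(getattr(base, key))(value)
        provenance[f"{section}.{key}"] = origin
    return replace(base, **kwargs)


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Mapping] | None = None,
) -> RunConfig:
    """Build a :class:`RunConfig` from defaults + optional file + overrides."""
    provenance: dict[str, str] = {}
    sections: dict[str, Any] = {name: cls() for name, cls in _SECTIONS.items()}
    scalars: dict[str, str] = {"builtin_detectors": "missing", "unknown_policy": "negative"}

    def apply(layer: Mapping, origin: str) -> None:
        for section, value in layer.items():
            if section in _SECTIONS:
                if not isinstance(value, Mapping):
                    raise ConfigError(f"section {section!r} must be a mapping")
                sections[section] = _merge_section(
                    _SECTIONS[section], sections[section], value, origin, provenance, section
                )
            elif section in _SCALARS:
                if value not in _SCALARS[section]:
                    raise ConfigError(
                        f"{section} must be one of {_SCALARS[section]}, got {value!r}"
                    )
                scalars[section] = value
                provenance[section] = origin
            else:
                raise ConfigError(
                    f"unknown config section {section!r}; valid: "
                    f"{sorted([*_SECTIONS, *_SCALARS])}"
                )

    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text())
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: config must be a mapping")
        apply(data, f"file:{path.name}")
    if overrides:
        apply(overrides, "override")

    return RunConfig(
        weights=sections["weights"],
        thresholds=sections["thresholds"],
        detectors=sections["detectors"],
        builtin_detectors=scalars["builtin_detectors"],
        unknown_policy=scalars["unknown_policy"],
        provenance=provenance,
    )


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Dump the effective configuration (plus provenance) as YAML."""
    payload = config.effective()
    if config.provenance:
        payload["provenance"] = dict(config.provenance)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
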
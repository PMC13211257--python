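"""Run configuration: defaults, TOML loading, validation, serialization.

The full reference configuration — 4 species with replication
probabilities (0.3, 0.5, 0.7, 0.9) on a 60x60 toroidal lattice, 5%
per-step mortality, 10% initial occupancy, 1000 steps, surveillance
always on with thresholds 0.70 (load) / 0.30 (dominance) and removal
fraction 0.80 — is encoded here as defaults, so an empty config file
reproduces it exactly.  Resolution order is defaults < file < explicit
overrides, and every run writes its fully resolved config to a JSON
sidecar so it can be reproduced from the sidecar alone.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

from .hexlattice import SpeciesParams, validate_roster
from .surveillance import Schedule, SurveillanceRule

DEFAULT_REPLICATION_PROBS: tuple[float, ...] = (0.3, 0.5, 0.7, 0.9)


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value; names the key."""


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one lattice simulation run."""

    width: int = 60
    height: int = 60
    initial_occupancy: float = 0.10
    replication_probs: tuple[float, ...] = DEFAULT_REPLICATION_PROBS
    mortality_prob: float = 0.05
    n_steps: int = 1000
    seed: int = 0
    rule: SurveillanceRule = field(default_factory=SurveillanceRule)
    schedule: Schedule = field(default_factory=Schedule)

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ConfigError(f"dynamics.n_steps must be >= 1, got {self.n_steps}")
        if not 0.0 <= self.mortality_prob < 1.0:
            raise ConfigError(
                f"dynamics.mortality must be in [0, 1), got {self.mortality_prob}"
            )
        if not 0.0 < self.initial_occupancy <= 1.0:
            raise ConfigError(
                "lattice.initial_occupancy must be in (0, 1], "
                f"got {self.initial_occupancy}"
            )
        validate_roster(self.species)
        for start, end in self.schedule.windows:
            if end > self.n_steps:
                raise ConfigError(
                    f"surveillance.windows: window [{start}, {end}) extends "
                    f"past n_steps = {self.n_steps}"
                )

    @property
    def species(self) -> list[SpeciesParams]:
        return [
            SpeciesParams(i + 1, p) for i, p in enumerate(self.replication_probs)
        ]

    @property
    def n_species(self) -> int:
        return len(self.replication_probs)

    def to_dict(self) -> dict[str, Any]:
        """Plain-dict form used for the JSON metadata sidecar."""
        return {
            "lattice": {
                "width": self.width,
                "height": self.height,
                "initial_occupancy": self.initial_occupancy,
            },
            "species": {"replication_probs": list(self.replication_probs)},
            "dynamics": {
                "mortality": self.mortality_prob,
                "n_steps": self.n_steps,
                "seed": self.seed,
            },
            "surveillance": {
                "mode": self.schedule.mode,
                "windows": [list(w) for w in self.schedule.windows],
                "load_threshold": self.rule.load_threshold,
                "dominance_threshold": self.rule.dominance_threshold,
                "removal_fraction": self.rule.removal_fraction,
                "target_policy": self.rule.target_policy,
            },
        }


# section -> key -> RunConfig attribute (or surveillance field)
_SCHEMA: dict[str, dict[str, str]] = {
    "lattice": {
        "width": "width",
        "height": "height",
        "initial_occupancy": "initial_occupancy",
    },
    "species": {"replication_probs": "replication_probs"},
    "dynamics": {
        "mortality": "mortality_prob",
        "n_steps": "n_steps",
        "seed": "seed",
    },
    "surveillance": {
        "mode": "mode",
        "windows": "windows",
        "load_threshold": "load_threshold",
        "dominance_threshold": "dominance_threshold",
        "removal_fraction": "removal_fraction",
        "target_policy": "target_policy",
    },
}
_RULE_KEYS = ("load_threshold", "dominance_threshold", "removal_fraction", "target_policy")
_SCHEDULE_KEYS = ("mode", "windows")


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    """Build a validated :class:`RunConfig` from a nested dict.

    Unknown sections or keys raise :class:`ConfigError` naming the key;
    so do out-of-range values (via the contained types' validation).
    """
    kwargs: dict[str, Any] = {}
    rule_kwargs: dict[str, Any] = {}
    schedule_kwargs: dict[str, Any] = {}
    for section, entries in data.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(entries, dict):
            raise ConfigError(f"section {section!r} must be a table of keys")
        for key, value in entries.items():
            if key not in _SCHEMA[section]:
                raise ConfigError(f"unknown config key {section}.{key!r}")
            attr = _SCHEMA[section][key]
            if section == "surveillance" and key in _RULE_KEYS:
                rule_kwargs[attr] = value
            elif section == "surveillance" and key in _SCHEDULE_KEYS:
                if key == "windows":
                    value = tuple(tuple(w) for w in value)
                schedule_kwargs[attr] = value
            elif key == "replication_probs":
                kwargs[attr] = tuple(float(p) for p in value)
            else:
                kwargs[attr] = value
    try:
        if rule_kwargs:
            kwargs["rule"] = SurveillanceRule(**rule_kwargs)
        if schedule_kwargs:
            kwargs["schedule"] = Schedule(**schedule_kwargs)
        return RunConfig(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration value: {exc}") from exc


def load_config(
    path: str | Path | None = None, overrides: dict[str, Any] | None = None
) -> RunConfig:
    """Load a TOML config file and apply dotted-key overrides.

    ``overrides`` maps dotted keys (``"dynamics.seed"``) to values and
    takes precedence over the file, which takes precedence over the
    built-in defaults.  ``path=None`` with no overrides yields the full
    default configuration.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    for dotted, value in (overrides or {}).items():
        section, _, key = dotted.partition(".")
        if not key:
            raise ConfigError(f"override key {dotted!r} must be 'section.key'")
        data.setdefault(section, {})[key] = value
    return config_from_dict(data)


def with_seed(config: RunConfig, seed: int) -> RunConfig:
    return replace(config, seed=int(seed))
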
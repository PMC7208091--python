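"""Flat key-value configuration handling for the CLI.

Accepts either a YAML mapping (``R: 5000``) or plain ``key=value`` lines.
Validation aggregates every violation into one report instead of stopping at
the first, and checks the cross-parameter constraint h >= F when enough keys
are present.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["ConfigError", "KNOWN_KEYS", "load_config", "validate_config", "canonical_echo"]

# key -> (type, validator, human-readable constraint)
_FLOAT_KEYS: dict[str, tuple[Any, str]] = {
    "R": (lambda v: v > 0, "R must be > 0"),
    "r_f": (lambda v: v > 0, "r_f must be > 0"),
    "r_m": (lambda v: v > 0, "r_m must be > 0"),
    "alpha": (lambda v: 0 < v < 1, "alpha must lie in (0,1)"),
    "w": (lambda v: 0 < v <= 1, "w must lie in (0,1]"),
    "h": (lambda v: v >= 1, "h must be >= 1"),
    "q": (lambda v: 0 < v <= 1, "q must lie in (0,1]"),
}
_INT_KEYS: dict[str, tuple[Any, str]] = {
    "reps": (lambda v: v >= 1, "reps must be >= 1"),
    "seed": (lambda v: v >= 0, "seed must be >= 0"),
}
KNOWN_KEYS = tuple(_FLOAT_KEYS) + tuple(_INT_KEYS)


class ConfigError(ValueError):
    """Aggregated validation report; ``violations`` lists every problem."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(violations))


def load_config(path: str | Path) -> dict[str, float | int]:
    """Read and validate a config file (YAML mapping or key=value lines)."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError:
        raw = None
    if not isinstance(raw, Mapping):
        raw = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError([f"cannot parse line {line!r} (expected key=value)"])
            k, v = (s.strip() for s in line.split("=", 1))
            raw[k] = v
    return validate_config(raw)


def validate_config(raw: Mapping[str, Any]) -> dict[str, float | int]:
    """Validate a flat mapping of parameters; returns the canonical dict.

    Unknown keys are rejected; every violated constraint is reported by name.
    """
    violations: list[str] = []
    out: dict[str, float | int] = {}
    for key, value in raw.items():
        if key not in KNOWN_KEYS:
            violations.append(f"unknown key {key!r} (known: {', '.join(KNOWN_KEYS)})")
            continue
        caster = int if key in _INT_KEYS else float
        try:
            cast = caster(value)
        except (TypeError, ValueError):
            violations.append(f"{key} must be a number, got {value!r}")
            continue
        check, msg = (_INT_KEYS if key in _INT_KEYS else _FLOAT_KEYS)[key]
        if not check(cast):
            violations.append(f"{msg}, got {cast:g}")
        else:
            out[key] = cast
    # cross-parameter structural constraint: F = alpha*R/r_f must fit into h
    if all(k in out for k in ("R", "r_f", "alpha", "h")):
        F = out["alpha"] * out["R"] / out["r_f"]
        if F > out["h"]:
            violations.append(
                f"F={F:g} > h={out['h']:g} violates the assumption h >= F"
            )
    if violations:
        raise ConfigError(violations)
    return out


def canonical_echo(config: Mapping[str, float | int]) -> str:
    """Canonical key=value rendering; re-parses to the identical mapping."""
    return "\n".join(f"{k}={config[k]!r}" for k in KNOWN_KEYS if k in config) + "\n"
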
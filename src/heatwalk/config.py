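"""Declarative configuration of the model settings.

Accepts either YAML (``.yaml``/``.yml``) or flat ``key=value`` lines.
Recognised keys: ``breakpoints`` (four comma-separated UTCI thresholds),
``h``, ``walking_speed``, ``time_quantum``, ``duration_rounding``,
``recovery_rate``, ``budget_m``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .errors import InvalidInputError
from .route_engine import DEFAULT_BUDGET_M
from .stress_model import HeatStressScale, ToleranceParams

__all__ = ["Settings", "load_config", "settings_from_config"]


@dataclass(frozen=True)
class Settings:
    scale: HeatStressScale
    params: ToleranceParams
    budget_m: float


def load_config(path) -> dict:
    """Parse a config file into a flat dict (YAML or key=value lines)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        cfg = yaml.safe_load(text) or {}
        if not isinstance(cfg, dict):
            raise InvalidInputError(f"{path}: config must be a mapping")
        return cfg
    cfg = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InvalidInputError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        cfg[key] = value
    return cfg


def _floats(value):
    if isinstance(value, (list, tuple)):
        return tuple(float(v) for v in value)
    return tuple(float(v) for v in str(value).split(","))


def settings_from_config(cfg: Optional[dict] = None) -> Settings:
    """Build model settings from a parsed config dict (defaults where absent)."""
    cfg = dict(cfg or {})
    known = {
        "breakpoints",
        "h",
        "walking_speed",
        "time_quantum",
        "duration_rounding",
        "recovery_rate",
        "budget_m",
    }
    unknown = set(cfg) - known
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    scale = (
        HeatStressScale(breakpoints=_floats(cfg["breakpoints"]))
        if "breakpoints" in cfg
        else HeatStressScale()
    )
    defaults = ToleranceParams()
    params = ToleranceParams(
        h=float(cfg.get("h", defaults.h)),
        walking_speed=float(cfg.get("walking_speed", defaults.walking_speed)),
        time_quantum=float(cfg.get("time_quantum", defaults.time_quantum)),
        duration_rounding=str(cfg.get("duration_rounding", defaults.duration_rounding)),
        recovery_rate=float(cfg.get("recovery_rate", defaults.recovery_rate)),
    )
    return Settings(scale=scale, params=params, budget_m=float(cfg.get("budget_m", DEFAULT_BUDGET_M)))
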
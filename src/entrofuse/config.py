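"""Flat key-value run configuration with file + override merging."""

from __future__ import annotations

from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .errors import ConfigError, MissingPathError
from .fusion import DEFAULT_EPSILON, ENTROPY_CONVENTIONS
from .metrics import DEFAULT_CALIBRATION_METRICS, SUPPORTED_METRICS

#: Defaults for every recognized configuration key.
DEFAULTS: Dict[str, Any] = {
    "metric_set": list(DEFAULT_CALIBRATION_METRICS),
    "entropy_convention": "normalized",
    "threshold": 0.5,
    "epsilon": DEFAULT_EPSILON,
}


def validate_config(cfg: Dict[str, Any]) -> Dict[str, Any]:
    unknown = set(cfg) - set(DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    metric_set = list(cfg["metric_set"])
    bad = [m for m in metric_set if m not in SUPPORTED_METRICS]
    if bad:
        raise ConfigError(f"unknown metrics in metric_set: {bad}")
    if not metric_set:
        raise ConfigError("metric_set must not be empty")
    if cfg["entropy_convention"] not in ENTROPY_CONVENTIONS:
        raise ConfigError(
            f"entropy_convention must be one of {ENTROPY_CONVENTIONS}"
        )
    if not 0.0 < float(cfg["threshold"]) <= 1.0:
        raise ConfigError("threshold must lie in (0, 1]")
    if float(cfg["epsilon"]) <= 0:
        raise ConfigError("epsilon must be > 0")
    cfg["metric_set"] = metric_set
    cfg["threshold"] = float(cfg["threshold"])
    cfg["epsilon"] = float(cfg["epsilon"])
    return cfg


def load_config(
    path: Optional[str] = None, overrides: Optional[Dict[str, Any]] = None
) -> Dict[str, Any]:
    """Merge defaults <- config file <- non-None overrides, then validate.

    The file is a flat YAML mapping; ``metric_set`` may be a list or a
    comma-separated string.
    """
    cfg = dict(DEFAULTS)
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise MissingPathError(f"config file not found: {p}")
        try:
            loaded = yaml.safe_load(p.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed config {p}: {exc}") from exc
        if not isinstance(loaded, dict):
            raise ConfigError(f"config {p} must be a flat mapping")
        cfg.update(loaded)
    for key, value in (overrides or {}).items():
        if value is not None:
            cfg[key] = value
    if isinstance(cfg.get("metric_set"), str):
        cfg["metric_set"] = [m.strip() for m in cfg["metric_set"].split(",") if m.strip()]
    return validate_config(cfg)
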
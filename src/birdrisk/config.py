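"""YAML run configuration shared by the CLI commands.

Recognised keys (all optional):

``class_middles``        mapping count-class label -> representative count
``alert_quantile``       calibration quantile for the alert threshold
``critical_quantile``    calibration quantile for the critical threshold
``alert_value``          fixed alert threshold (skips calibration)
``critical_value``       fixed critical threshold
``floor_ratio``          strike ratio for counted-but-never-struck species
``density_eligibility``  minimum density for the floor rule
``floor_mode``           "constant" or "from_movements"
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .bsri import ClassMiddleMap, ThresholdConfig
from .ssi import SSIConfig

__all__ = ["RunConfig", "load_config"]

_KNOWN_KEYS = {
    "class_middles",
    "alert_quantile",
    "critical_quantile",
    "alert_value",
    "critical_value",
    "floor_ratio",
    "density_eligibility",
    "floor_mode",
}


@dataclass
class RunConfig:
    ssi: SSIConfig
    middles: ClassMiddleMap
    #: fixed thresholds, or None to calibrate from the data at the quantiles
    thresholds: ThresholdConfig | None
    alert_quantile: float = 0.80
    critical_quantile: float = 0.95


def load_config(path=None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file (or defaults)."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

    ssi = SSIConfig(
        floor_ratio=raw.get("floor_ratio", 0.0035),
        density_eligibility=raw.get("density_eligibility", 0.001),
        floor_mode=raw.get("floor_mode", "constant"),
    )
    middles = (
        ClassMiddleMap(raw["class_middles"]) if "class_middles" in raw else ClassMiddleMap()
    )
    alert_q = raw.get("alert_quantile", 0.80)
    critical_q = raw.get("critical_quantile", 0.95)
    thresholds = None
    if "alert_value" in raw or "critical_value" in raw:
        thresholds = ThresholdConfig(
            alert_quantile=alert_q,
            critical_quantile=critical_q,
            alert_value=raw.get("alert_value", 3.1),
            critical_value=raw.get("critical_value", 3.7),
        )
    return RunConfig(
        ssi=ssi,
        middles=middles,
        thresholds=thresholds,
        alert_quantile=alert_q,
        critical_quantile=critical_q,
    )
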
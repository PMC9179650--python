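"""YAML configuration for the pipeline and simulator.

One file configures everything; every section is optional and falls back to
the documented defaults.  Example::

    classifier:
      heading_return_tol: 10
      glide_window: 20
    aero:
      base_sink_rate: -0.75
      bank_angle: 25
      lift_drag_ratio: 15
    migration_heading: 20
    smooth_window: 3
    policy:
      tas: 11.4
      circle_period: 22
    waves:
      - amplitude: 2.8
        wavelength: 10000
        z0: 2000
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._errors import ConfigurationError
from .aero import AeroConfig
from .maneuvers import ClassifierConfig
from .synthetic_flight import FlightPolicy, WaveField, default_wave_fields

__all__ = ["PipelineConfig", "load_config"]


def _build(cls, data: dict, what: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown {what} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class PipelineConfig:
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    aero: AeroConfig = field(default_factory=AeroConfig)
    policy: FlightPolicy = field(default_factory=FlightPolicy)
    waves: tuple[WaveField, ...] = field(default_factory=default_wave_fields)
    migration_heading: float = 20.0
    smooth_window: int = 3
    tailwind: float | None = None       # override; None -> circle-derived
    direct_distance_m: float | None = None

    def digest(self) -> str:
        """Stable hash of the configuration, for run provenance."""
        payload = {
            "classifier": dataclasses.asdict(self.classifier),
            "aero": dataclasses.asdict(self.aero),
            "policy": dataclasses.asdict(self.policy),
            "waves": [dataclasses.asdict(w) for w in self.waves],
            "migration_heading": self.migration_heading,
            "smooth_window": self.smooth_window,
            "tailwind": self.tailwind,
            "direct_distance_m": self.direct_distance_m,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a :class:`PipelineConfig`; ``None`` gives all defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    kwargs = {}
    if "classifier" in raw:
        kwargs["classifier"] = _build(ClassifierConfig, raw.pop("classifier"), "classifier")
    if "aero" in raw:
        kwargs["aero"] = _build(AeroConfig, raw.pop("aero"), "aero")
    if "policy" in raw:
        pol = raw.pop("policy")
        if "wind_profile" in pol:
            pol["wind_profile"] = tuple(tuple(p) for p in pol["wind_profile"])
        kwargs["policy"] = _build(FlightPolicy, pol, "policy")
    if "waves" in raw:
        kwargs["waves"] = tuple(_build(WaveField, w, "wave") for w in raw.pop("waves"))
    for key in ("migration_heading", "smooth_window", "tailwind", "direct_distance_m"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise ConfigurationError(f"{path}: unknown top-level keys {sorted(raw)}")
    return PipelineConfig(**kwargs)
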
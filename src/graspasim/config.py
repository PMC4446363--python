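"""Structured configuration: validated parameters with field defaults.

A run is fully described by a small YAML file with up to five sections
(``photosynthesis``, ``growth``, ``management``, ``protocol``, ``forcing``)
plus a top-level ``alpha``.  Every parameter has a scientifically motivated
default (e.g. Vcmax/Jmax 55/110 umol m-2 s-1, nitrogen-response a=0.75 and
N_addmax=0.6, SLA_max 0.048 m2 gC-1, intake capacity 13 kg DM LSU-1 d-1,
alpha=0.2), so an empty file is a valid configuration.  Unknown keys are
rejected with a field-level message rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .adaptive_management import DEFAULT_ALPHA
from .experiments import ProtocolConfig
from .grass_growth import GrowthParams, PhotosynthesisParams
from .management import ManagementParams


@dataclass(frozen=True)
class ForcingConfig:
    """Synthetic-forcing geometry and driver settings."""

    n_lat: int = 10
    n_lon: int = 10
    years: int = 70
    seed: int = 0
    start_year: int = 1901
    co2_base_ppm: float = 296.0
    co2_growth: float = 1.0          # ppm per year (linear mode)
    co2_mode: str = "linear"
    organic_n: float = 20.0          # kg N ha-1 yr-1, constant in time
    mineral_n_reference: float = 50.0  # reference (1961) application rate
    deposition_n: float = 8.0

    def __post_init__(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1 or self.years < 1:
            raise ValueError("grid dimensions and years must be >= 1")


@dataclass
class Config:
    photosynthesis: PhotosynthesisParams = field(
        default_factory=PhotosynthesisParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    management: ManagementParams = field(default_factory=ManagementParams)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    forcing: ForcingConfig = field(default_factory=ForcingConfig)
    alpha: float = DEFAULT_ALPHA

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "photosynthesis": PhotosynthesisParams,
    "growth": GrowthParams,
    "management": ManagementParams,
    "protocol": ProtocolConfig,
    "forcing": ForcingConfig,
}


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) in section {section!r}: {sorted(unknown)}; "
            f"valid keys: {sorted(valid)}")
    return cls(**data)


def config_from_dict(raw: dict | None) -> Config:
    """Validated Config from a (possibly empty) mapping."""
    raw = dict(raw or {})
    alpha = raw.pop("alpha", DEFAULT_ALPHA)
    if not 0.0 <= float(alpha) <= 1.0:
        raise ValueError(f"alpha must be in [0,1], got {alpha}")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}; "
                         f"valid sections: {sorted(_SECTIONS)} and 'alpha'")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        data = raw.get(section) or {}
        if not isinstance(data, dict):
            raise ValueError(f"section {section!r} must be a mapping")
        kwargs[section] = _build_section(cls, data, section)
    cfg = Config(alpha=float(alpha), **kwargs)
    cfg.protocol.alpha = cfg.alpha
    return cfg


def load_config(path: str | Path | None) -> Config:
    """Load and validate a YAML configuration; ``None`` gives all defaults."""
    if path is None:
        return config_from_dict({})
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    return config_from_dict(raw)
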
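"""Pipeline configuration: one YAML document, strict keys, one seed.

The nested blocks mirror the parameter objects of each stage
(detection, linking, event calling, statistics, simulators).  Defaults
reproduce the assay's stated constants: 15% intensity threshold, 0.2
circularity, 60–200 nm diameter band, a 3 SD drop over the last 5 time
points with a 5-frame disappearance window, 150 frames at 0.1 s.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detect import DetectionParams
from .events import EventParams
from .simulate import FluorSimConfig, TirfSimConfig
from .stats import CROSS_CAP_DEFAULT
from .track import LinkParams

__all__ = ["StatsOptions", "PipelineConfig", "load_config", "save_config",
           "config_hash"]


@dataclass
class StatsOptions:
    cross_cap: int = CROSS_CAP_DEFAULT
    p_mode: str = "tail"          # tail | pmf
    band68: tuple[float, float] = (16.0, 84.0)
    band95: tuple[float, float] = (2.5, 97.5)


@dataclass
class PipelineConfig:
    seed: int = 0
    detection: DetectionParams = field(default_factory=DetectionParams)
    linking: LinkParams = field(default_factory=LinkParams)
    events: EventParams = field(default_factory=EventParams)
    stats: StatsOptions = field(default_factory=StatsOptions)
    tirf_sim: TirfSimConfig = field(default_factory=TirfSimConfig)
    fluor_sim: FluorSimConfig = field(default_factory=FluorSimConfig)


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in config block {path!r}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if isinstance(value, dict) and f.name in _NESTED:
            value = _build(_NESTED[f.name], value, f"{path}.{f.name}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


_NESTED = {
    "detection": DetectionParams,
    "linking": LinkParams,
    "events": EventParams,
    "stats": StatsOptions,
    "tirf_sim": TirfSimConfig,
    "fluor_sim": FluorSimConfig,
}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config, rejecting unknown keys."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _build(PipelineConfig, data, "pipeline")


def save_config(path: str | Path, config: PipelineConfig) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config),
                                         sort_keys=True))


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of the fully resolved configuration."""
    canonical = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
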
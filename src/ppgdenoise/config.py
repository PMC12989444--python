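"""Pipeline configuration: every numeric default in one serializable place.

The config round-trips losslessly through YAML (the single supported
dialect).  A config file may also carry a ``scenario`` section consumed
by the simulator CLI; sections absent from the file keep their defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .bss import BSSConfig
from .errors import FormatError
from .synthwave import ScenarioConfig

__all__ = [
    "PreprocessConfig",
    "FrameConfig",
    "EntropyConfig",
    "GridConfig",
    "FilterConfig",
    "HRConfig",
    "PipelineConfig",
    "FullConfig",
    "load_config",
    "save_config",
]


@dataclass
class PreprocessConfig:
    lo_hz: float = 0.5
    hi_hz: float = 5.0
    order: int = 4  # analog prototype order (2*order poles in the band-pass)
    zero_phase: bool = False


@dataclass
class FrameConfig:
    len_s: float = 8.0
    hop_s: float = 8.0
    min_partial_s: float = 4.0


@dataclass
class EntropyConfig:
    band_hz: tuple = (0.5, 5.0)
    eps: float = 1e-12
    threshold: float = 2.0  # HT, bits
    band_width_hz: float = 0.5  # sub-band aggregation width for the PSD


@dataclass
class GridConfig:
    soft_mu: tuple = (3e-4, 4e-4, 5e-4, 6e-4, 7e-4)
    soft_N: tuple = (25, 30, 35, 40, 45, 50)
    hard_mu: tuple = (8e-4, 9e-4, 1e-3, 1.1e-3, 1.2e-3, 1.3e-3, 1.4e-3, 1.5e-3)
    hard_N: tuple = (51, 60, 70, 80, 90, 100, 110, 120)


@dataclass
class FilterConfig:
    # reference sequences are standardized to this SD before filtering so
    # the mode grids' learning rates act at a known loop gain mu*N*P_ref
    reference_std: float = 0.1
    grid_epochs: int = 3  # adaptation passes per grid candidate
    max_epochs: int = 50  # cap for the steady-state emission pass
    he_tol: float = 0.01  # He plateau tolerance (bits) stopping the epochs


@dataclass
class HRConfig:
    window_s: float = 8.0
    max_lag_s: float = 2.0
    prominence_frac: float = 0.3


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    frame: FrameConfig = field(default_factory=FrameConfig)
    bss: BSSConfig = field(default_factory=BSSConfig)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    grids: GridConfig = field(default_factory=GridConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    hr: HRConfig = field(default_factory=HRConfig)


@dataclass
class FullConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)


def _to_plain(obj):
    """Dataclass tree -> plain dict/list tree (tuples become lists)."""
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    return obj


_NESTED = {
    PipelineConfig: {
        "preprocess": PreprocessConfig, "frame": FrameConfig, "bss": BSSConfig,
        "entropy": EntropyConfig, "grids": GridConfig, "filter": FilterConfig,
        "hr": HRConfig,
    },
    FullConfig: {"scenario": ScenarioConfig, "pipeline": PipelineConfig},
}


def _resolve(cls, name):
    return _NESTED.get(cls, {}).get(name)


def _from_plain(cls, data: dict):
    """Rebuild a dataclass tree from a plain dict, validating key names."""
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise FormatError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        sub = _resolve(cls, name)
        if sub is not None:
            kwargs[name] = _from_plain(sub, value or {})
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: Optional[str | Path] = None) -> FullConfig:
    """Load scenario + pipeline config from YAML; missing path or missing
    sections yield defaults."""
    if path is None:
        return FullConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: top level must be a mapping")
    return _from_plain(FullConfig, raw)


def save_config(config: FullConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(_to_plain(config), sort_keys=False)
    )
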
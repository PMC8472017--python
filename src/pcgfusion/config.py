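"""Pipeline parameters and YAML (de)serialisation.

All times are seconds internally; parameters that the method literature
states in milliseconds or in samples keep their native unit in the field
name (``*_s``, ``*_n``, ``*_samples``) so the YAML file reads naturally.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: Canonical processing rates. PCG analysis assumes a 1 kHz grid (the
#: entropy window of 20 samples then spans 20 ms); the PPG channel is
#: processed at 100 Hz so that "10 samples" of peak-search spread spans
#: 100 ms. Inputs at other rates are resampled on load.
PCG_FS_HZ = 1000.0
PPG_FS_HZ = 100.0


@dataclass
class PcgParams:
    """Parameters of the PCG envelope-segmentation chain."""

    band_low_hz: float = 20.0
    band_high_hz: float = 200.0
    filter_order: int = 4
    floor_frac: float = 0.05
    entropy_window_n: int = 20
    smooth_window_s: float = 0.050
    gate_offset: float = 0.01
    min_dur_s: float = 0.030
    max_dur_s: float = 0.250
    merge_gap_s: float = 0.020
    fs_hz: float = PCG_FS_HZ


@dataclass
class PpgParams:
    """Parameters of the PPG delineation chain."""

    band_low_hz: float = 0.5
    band_high_hz: float = 5.0
    filter_order: int = 2
    target_crossings: float = 10.0
    smooth_cap_s: float = 0.25
    entropy_window_n: int = 20
    env_smooth_s: float = 0.25
    candidate_rel_threshold: float = 0.2
    peak_spread_samples: int = 10
    fs_hz: float = PPG_FS_HZ


@dataclass
class FusionParams:
    """Timing windows of the S1/S2 identification rule (seconds)."""

    s1_max_lead_s: float = 0.500
    s2_window_s: float = 0.020


@dataclass
class EvalParams:
    match_tol_s: float = 0.010


@dataclass
class PipelineConfig:
    pcg: PcgParams = field(default_factory=PcgParams)
    ppg: PpgParams = field(default_factory=PpgParams)
    fusion: FusionParams = field(default_factory=FusionParams)
    eval: EvalParams = field(default_factory=EvalParams)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _update_dataclass(obj: Any, values: dict[str, Any], section: str) -> None:
    names = {f.name for f in dataclasses.fields(obj)}
    for key, val in values.items():
        if key not in names:
            raise KeyError(f"unknown parameter {key!r} in config section {section!r}")
        setattr(obj, key, val)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML; missing keys keep defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for section in ("pcg", "ppg", "fusion", "eval"):
        if section in data and data[section] is not None:
            _update_dataclass(getattr(cfg, section), data[section], section)
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
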
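"""TOML-backed configuration of the analysis defaults.

Every tunable named by the pipeline is exposed here so a study can pin its
settings in one file.  Units: window sizes and radii in pixels, fractions
dimensionless, strengths in [0, 1].
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    # landmark tracking
    tracking_window: int = 96
    peak_ratio_threshold: float = 1.2
    track_max_step: float = 10.0
    track_smoothing: float = 0.0
    # registration / ROI
    roi_factor: float = 1.3
    taper_fraction: float = 0.25
    # LTC kernel
    apodization_margin: float = 0.1
    scan_band_lo: float = 0.06  # cycles/px
    scan_band_hi: float = 0.25
    row_filter_strength: float = 0.0
    max_failed_fraction: float = 0.25
    # baselines
    ste_window: int = 32
    ste_overlap: float = 0.75


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig`, overriding defaults from TOML.

    Unknown keys raise, to catch typos in study configs.
    """
    cfg = AnalysisConfig()
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in fields(AnalysisConfig)}
    for key, value in data.items():
        if key not in known:
            raise KeyError(f"unknown configuration key {key!r}")
        setattr(cfg, key, value)
    return cfg
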
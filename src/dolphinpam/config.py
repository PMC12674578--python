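"""Pipeline configuration with the study's default parameters.

Every stage parameter lives here with its default: 5th-order 3 kHz
Butterworth high-pass, 2-ms SNR window, ICI category bounds 0.017/0.22 s,
whistle duration-class bounds 0.2/0.4/0.8 s, KDE bandwidth 0.4, 300-s
blocks, and the 05:00-07:00 exclusion window.  A YAML file can override
any field; overrides are logged so the effective parameter set of a run is
auditable.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

log = logging.getLogger("dolphinpam")

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    filter_order: int = 5
    filter_cutoff_hz: float = 3000.0
    snr_window_ms: float = 2.0
    noise_segment: tuple[float, float] | None = None  # None -> auto (min-variance 1 s)
    th_db: float | None = None  # None -> sensitivity-curve knee
    peak_mode: str = "isolated"
    max_gap_s: float = 2.0
    min_peaks: int = 3
    ici_fb_max_s: float = 0.017
    ici_bps_max_s: float = 0.22
    class_bounds_s: tuple[float, float, float] = (0.2, 0.4, 0.8)
    kde_bandwidth: float = 0.4
    kde_bandwidth_mode: str = "absolute"
    block_length_s: int = 300
    exclusion_windows: list | None = None  # None -> the default 05:00-07:00 window

    @property
    def snr_window_s(self) -> float:
        return self.snr_window_ms / 1000.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load overrides from YAML; unknown keys are an error, overrides logged."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls()
        for key, value in data.items():
            default = getattr(cfg, key)
            if isinstance(default, tuple) and isinstance(value, list):
                value = tuple(value)
            setattr(cfg, key, value)
            log.info("config override: %s = %r (default %r)", key, value, default)
        return cfg

    def log_effective(self) -> None:
        """Log the full effective parameter set (auditability of Th etc.)."""
        for key, value in asdict(self).items():
            log.info("param %s = %r", key, value)
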
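"""Analysis configuration: one flat set of documented defaults.

Every tunable of the pipeline lives here so a session analysis is fully
described by (data, config, seed). ``config_hash`` is stored with every
result table for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "load_config", "config_hash"]


@dataclass
class AnalysisConfig:
    """All analysis parameters with their defaults.

    Units are part of the field names where they matter. The defaults are
    the protocol values used throughout: 2 cm/s movement threshold, 5-cm
    spatial bins (10-cm bins for population vectors), 1 cm/s speed bins,
    1000 circular shuffles with a >95% significance criterion, and a
    transient false-positive target below 5%.
    """

    # --- track / recording geometry ---
    track_length_cm: float = 400.0
    fs_hz: float = 10.0
    circular_track: bool = True

    # --- movement / binning ---
    speed_threshold_cm_s: float = 2.0
    spatial_bin_cm: float = 5.0
    pv_bin_cm: float = 10.0          # coarser bins, population vectors only
    speed_bin_cm_s: float = 1.0
    min_speed_bin_time_s: float = 1.0

    # --- dF/F extraction ---
    dff_window_s: float = 8.0
    dff_percentile: float = 8.0
    baseline_sd_cut: float = 3.0     # initial baseline: points <= mean + cut*SD

    # --- transient detection / calibration ---
    fpr_target: float = 0.05         # negative/positive transient ratio
    onset_grid_sd: tuple[float, ...] = (2.0, 2.5, 3.0, 3.5, 4.0)
    duration_grid_s: tuple[float, ...] = (0.2, 0.3, 0.5, 1.0)
    offset_fraction: float = 0.5     # event ends below this fraction of onset level

    # --- significance ---
    n_shuffles: int = 1000
    min_shift_s: float = 10.0
    significance_percentile: float = 95.0
    alpha: float = 0.05

    # --- place cells / remapping ---
    place_cell_min_rate_per_min: float = 1.0
    min_place_cells_per_condition: int = 5
    field_corr_bin_cm: float = 5.0

    # --- statistics hygiene ---
    outlier_iqr_k: float = 3.0

    def __post_init__(self) -> None:
        positive = [
            "track_length_cm", "fs_hz", "spatial_bin_cm", "pv_bin_cm",
            "speed_bin_cm_s", "dff_window_s", "fpr_target", "offset_fraction",
            "min_shift_s", "place_cell_min_rate_per_min", "outlier_iqr_k",
            "field_corr_bin_cm",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0 < self.dff_percentile < 100:
            raise ValueError("dff_percentile must be in (0, 100)")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.significance_percentile < 100:
            raise ValueError("significance_percentile must be in (0, 100)")

    @property
    def n_spatial_bins(self) -> int:
        import math
        return math.ceil(self.track_length_cm / self.spatial_bin_cm)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["onset_grid_sd"] = list(d["onset_grid_sd"])
        d["duration_grid_s"] = list(d["duration_grid_s"])
        return d

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML key-value file.

    An empty file (or one containing only comments) yields all defaults.
    Unknown keys raise with the list of valid keys.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    valid = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    for key in ("onset_grid_sd", "duration_grid_s"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return AnalysisConfig(**raw)


def config_hash(cfg: AnalysisConfig) -> str:
    """Stable short hash of the fully resolved configuration."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha1(payload).hexdigest()[:12]
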
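"""Pipeline configuration.

One flat record of every numeric knob in the chain, each at its published
default, plus stage toggles, a root seed and IO paths. Unknown keys in a YAML
file are rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # stage toggles
    run_qc: bool = True
    run_bursts: bool = True
    run_velocity: bool = True
    run_clustering: bool = True
    run_connectivity: bool = True
    run_tracking: bool = False

    # QC
    refractory_ms: float = 1.0
    refractory_max_fraction: float = 0.05
    duplicate_window_ms: float = 0.5
    duplicate_radius_um: float = 100.0
    min_spikes_per_unit: int = 50
    ef_min_spikes: int = 30
    ef_pre_ms: float = 2.0
    ef_post_ms: float = 3.0

    # burst detection / spectra
    mua_bin_s: float = 0.1
    mua_smooth_sd_s: float = 0.3
    burst_min_duration_s: float = 0.5
    lfp_fs_hz: float = 1000.0
    welch_segment_s: float = 1.0
    psd_f_range_hz: tuple = (2.0, 100.0)
    min_peak_power: float = 0.3

    # waveform clustering
    cluster_resolution: float = 1.5
    cluster_n_neighbors: int = 15
    cluster_min_dist: float = 0.1
    sweep_n_iter: int = 20

    # axonal velocity
    velocity_max_edge_um: float = 60.0
    velocity_min_r2: float = 0.8
    velocity_noise_mad_factor: float = 5.0
    velocity_subsample_interp: bool = False

    # connectivity
    ccg_bin_ms: float = 1.0
    ccg_lag_ms: float = 50.0
    ccg_conv_sd_ms: float = 10.0
    ccg_window_ms: float = 5.0
    alpha: float = 0.001
    te_history_target: int = 1
    te_history_source: int = 4
    te_delay_bins: int = 1
    te_n_surrogates: int = 50
    te_jitter_bins: int = 7
    te_scales_ms: tuple = (1.0, 1.6, 3.5, 7.4, 16.0, 35.0, 74.0, 160.0)

    # tracking
    tracking_sim_threshold: float = 0.85

    seed: int = 0
    in_dir: str = "."
    out_dir: str = "out"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["psd_f_range_hz"] = list(d["psd_f_range_hz"])
        d["te_scales_ms"] = list(d["te_scales_ms"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "psd_f_range_hz" in raw:
            raw["psd_f_range_hz"] = tuple(raw["psd_f_range_hz"])
        if "te_scales_ms" in raw:
            raw["te_scales_ms"] = tuple(raw["te_scales_ms"])
        return cls(**raw)
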
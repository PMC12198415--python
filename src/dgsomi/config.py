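"""Pipeline configuration.

A single flat mapping of every tunable the pipeline uses, with defaults.
Round-trips losslessly through YAML; unknown keys are rejected so that typos
in config files fail loudly instead of silently using a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # -- session geometry / timing conventions --------------------------------
    track_length_cm: float = 400.0
    pre_zone_s: float = 2.0
    post_zone_s: float = 2.0
    #: baseline window relative to reward onset, seconds
    baseline_window_s: tuple[float, float] = (-6.0, -4.0)

    # -- behavior -------------------------------------------------------------
    immobility_speed_cms: float = 0.5
    locomotion_speed_cms: float = 3.0
    min_immobility_s: float = 3.0
    max_transition_s: float = 3.0
    behavior_alpha: float = 0.05
    min_rewarded_laps: int = 10

    # -- unit classification --------------------------------------------------
    acg_bin_ms: float = 1.0
    acg_max_lag_ms: float = 300.0
    bursting_threshold: float = 3.0
    trough_to_peak_threshold_ms: float = 0.45
    kmeans_restarts: int = 50

    # -- opto-tagging ---------------------------------------------------------
    opto_alpha: float = 0.05
    opto_min_pulses: int = 20
    somi_latency_ms: float = 5.0

    # -- connectivity ---------------------------------------------------------
    ccg_bin_ms: float = 0.5
    ccg_max_lag_ms: float = 50.0
    ccg_kernel_sigma_ms: float = 10.0
    ccg_hollow_fraction: float = 0.6
    ccg_quantile: float = 0.999
    causal_window_ms: tuple[float, float] = (1.2, 4.0)

    # -- event responses ------------------------------------------------------
    align_window_s: tuple[float, float] = (-5.0, 5.0)
    align_bin_s: float = 0.1
    smooth_sigma_bins: float = 1.0
    modulation_alpha: float = 0.05
    min_modulation_trials: int = 10
    delay_search_window_s: tuple[float, float] = (-2.0, 2.0)
    onoff_min_transitions: int = 8
    onoff_windows_s: tuple[float, float, float, float] = (-3.0, -1.0, 1.0, 3.0)
    speed_regression_bin_s: float = 0.1
    sensory_min_events: int = 15

    # -- GLM encoding ---------------------------------------------------------
    glm_window_s: tuple[float, float] = (-3.0, 3.0)
    glm_n_bins: int = 24
    glm_folds: int = 5
    glm_n_permutations: int = 500
    glm_quantile: float = 0.95

    # -- ML decoder -----------------------------------------------------------
    kde_bandwidth_s: float = 0.2
    kde_grid_s: float = 0.05
    loglik_bin_s: float = 0.25
    rate_floor_hz: float = 0.1
    expectation_window_s: tuple[float, float] = (-1.5, 1.5)
    baseline_period_s: tuple[float, float] = (-4.25, -1.5)
    decode_lengths_s: tuple[float, ...] = tuple(0.25 * k for k in range(1, 12))
    decode_n_shuffles: int = 500
    decode_shuffle_quantile: float = 0.99
    decode_subset_draws: int = 50
    min_decoder_rate_hz: float = 1.0 / 1.5

    # -- global ---------------------------------------------------------------
    seed: int = 0

    # ------------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name: f.type for f in fields(cls)}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for k, v in d.items():
            default = getattr(cls, k, None)
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
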
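"""Pipeline configuration: every numeric constant, namespaced and overridable.

Defaults equal the published processing parameters (50 Hz working rate,
Savitzky-Golay (2, 61), 10% missing-data exclusion, the straight-walking
criteria, the turn thresholds, the k-means and stillness settings).  A YAML
file with the same nesting overrides individual keys; unknown keys are
rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import InputError


@dataclass
class PreprocessConfig:
    target_rate: float = 50.0
    savgol_window: int = 61
    savgol_window_vertical: int = 11
    savgol_order: int = 2
    max_missing_frac: float = 0.10
    xcorr_max_lag_s: float = 5.0
    min_overlap_s: float = 1.0


@dataclass
class GaitConfig:
    min_speed: float = 0.5            # m/s, criterion (4)
    max_heading_range: float = 45.0   # deg, criterion (2)
    max_yaw_range: float = 45.0       # deg, criterion (3)
    min_length_m: float = 2.0         # m, criterion (1)
    arc_step_m: float = 0.01
    speed_ma_window_s: float = 0.5
    mdht_prominence: float = 0.01
    mdht_min_dist_s: float = 0.5
    mdht_search_s: tuple = (0.05, 0.5)
    mdht_min_drop: float = 0.04
    mdht_max_abs: float = 0.05
    ds_prominence: float = 0.001
    ds_min_dist_frames: int = 13
    ds_band_hz: tuple = (1.5, 3.5)
    butter_order: int = 2


@dataclass
class TurningConfig:
    impulse_dur_s: float = 1.5
    min_depth: float = 20.0
    ve: float = 50.0
    ar_vx: float = 26.0
    ar_vc: float = 16.0
    ref_vx: float = 18.0
    ref_vc: float = 39.0


@dataclass
class SquatConfig:
    prominence_m: float = 0.02
    min_dist_s: float = 1.0
    group_window_s: float = 8.0
    kmeans_iters: int = 10
    vel_tol: float = 0.001
    vel_window: int = 5


@dataclass
class TransferConfig:
    speed_threshold: float = 0.001
    min_centroid_gap: float = 0.1
    kmeans_iters: int = 10
    vel_window: int = 5


@dataclass
class MatchingConfig:
    min_overlap: float = 0.5


#: Which motor-state detectors run for each exercise context.
DEFAULT_GAMES = {
    "walk": ["straight_walking"],
    "walk_turn": ["straight_walking", "turning"],
    "squat": ["straight_walking", "squatting"],
    "transfer": ["straight_walking", "transfers"],
    "mixed": ["straight_walking", "turning", "squatting"],
}


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    gait: GaitConfig = field(default_factory=GaitConfig)
    turning: TurningConfig = field(default_factory=TurningConfig)
    squats: SquatConfig = field(default_factory=SquatConfig)
    transfers: TransferConfig = field(default_factory=TransferConfig)
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    games: dict = field(default_factory=lambda: dict(DEFAULT_GAMES))

    def states_for(self, game: str) -> list[str]:
        return self.games.get(game, ["straight_walking"])


def _apply(obj, overrides: dict, path: str = ""):
    for key, val in overrides.items():
        if not hasattr(obj, key):
            raise InputError(f"unknown config key {path + key!r}")
        cur = getattr(obj, key)
        if dataclasses.is_dataclass(cur) and isinstance(val, dict):
            _apply(cur, val, path + key + ".")
        elif isinstance(cur, tuple) and isinstance(val, (list, tuple)):
            setattr(obj, key, tuple(val))
        else:
            setattr(obj, key, val)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Build a config from defaults, an optional YAML file and a dict."""
    cfg = PipelineConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a mapping")
        _apply(cfg, data)
    if overrides:
        _apply(cfg, overrides)
    return cfg
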
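"""Run configuration: column mapping, timezone, and every numeric threshold
used by the extraction/clustering pipeline.

Defaults mirror the published barn-owl protocol: accuracy filter STD > 50 m,
speed filter > 15 m/s, diel windows from 10:00 to 10:00 local time, complete
nights need > 1000 fixes starting before 21:00 and ending after 02:00,
individuals need > 30 complete nights, endpoints average n = 20 fixes, and
trajectories are subsampled to one point per 5 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

from .errors import ConfigError

DEFAULT_COLUMNS = {
    "individual_id": "individual_id",
    "timestamp": "timestamp",
    "x": "x",
    "y": "y",
    "accuracy_std": "accuracy_std",
}


@dataclass
class RunConfig:
    # --- IO ---
    columns: dict = field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    delimiter: str = ","
    timezone: str = "Asia/Jerusalem"

    # --- fix filtering ---
    max_std: float = 50.0          # m; drop fixes with accuracy STD above this
    max_speed: float = 15.0        # m/s; drop fixes implying faster movement

    # --- diel segmentation & night quality ---
    boundary_hour: int = 10        # local clock hour opening each diel window
    min_fixes: int = 1000          # strict >, per night
    latest_start_hour: float = 21.0   # first fix must be before this (local)
    earliest_end_hour: float = 2.0    # last fix must be after this, next day
    min_nights: int = 30           # strict >, complete nights per individual
    count_after_filtering: bool = True  # apply min_fixes after accuracy/speed filters

    # --- endpoints, flight segmentation, subsampling ---
    endpoint_n: int = 20
    flight_window_s: float = 60.0
    flight_speed_threshold: float = 2.0   # m/s median speed => move
    flight_min_run_s: float = 60.0
    subsample_s: float = 300.0

    # --- clustering / PCA ---
    k: int = 7
    k_max: int = 15
    open_lo_km: float = 0.25       # openness labels: closed < lo <= partial < hi <= wide
    open_hi_km: float = 2.0

    # --- cohort analyses ---
    kmeans_k: int = 3
    kmeans_restarts: int = 25
    seed: int = 0
    exclude_no_flight: bool = True  # drop all-night nest stays from the size model

    def __post_init__(self) -> None:
        positive = [
            "max_std", "max_speed", "min_fixes", "min_nights", "endpoint_n",
            "flight_window_s", "flight_speed_threshold", "flight_min_run_s",
            "subsample_s", "k", "k_max", "kmeans_k", "kmeans_restarts",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"config value {name!r} must be positive")
        if not 0 <= self.boundary_hour < 24:
            raise ConfigError("boundary_hour must be a clock hour in [0, 24)")
        missing = set(DEFAULT_COLUMNS) - {"accuracy_std"} - set(self.columns)
        if missing:
            raise ConfigError(f"column mapping lacks required keys: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "columns" in raw:
            cols = dict(DEFAULT_COLUMNS)
            cols.update(raw["columns"])
            raw = {**raw, "columns": cols}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
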
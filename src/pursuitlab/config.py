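"""Run configuration: every tunable analysis decision in one serialisable
object, round-tripping losslessly through YAML."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "GeometryConfig",
    "SessionConfig",
    "SimulatorConfig",
    "PreprocessConfig",
    "MetricsConfig",
    "StatsConfig",
    "RunConfig",
]


@dataclass
class GeometryConfig:
    separation_deg: float = 6.0
    eccentricity_deg: float = 3.0
    window_sd_deg: float = 0.4
    dot_density: float = 0.5
    presentation_ms: float = 500.0


@dataclass
class SessionConfig:
    n_per_cell: int = 20
    n_blocks: int = 5
    velocities: list[float] = field(default_factory=lambda: [3.0, 4.0, 5.0])
    cue_ms: float = 2500.0
    pretrial_range_ms: list[float] = field(default_factory=lambda: [1000.0, 1500.0])
    intertrial_ms: float = 5000.0


@dataclass
class SimulatorConfig:
    n_observers: int = 12
    jitter_observers: bool = True
    population_overrides: dict = field(default_factory=dict)


@dataclass
class PreprocessConfig:
    fir_taps: int = 80
    fir_passband_hz: float = 30.0
    fs_hz: float = 1000.0
    zero_phase: bool = True  # forward-backward filtering (no lag)
    accel_from_filtered: bool = True  # differentiate filtered vs raw velocity
    saccade_v_thr: float = 30.0
    saccade_a_thr: float = 1000.0
    # pad > the nominal 10 ms: zero-phase FIR filtering smears saccade
    # signatures well beyond the threshold-crossing span
    saccade_pad_ms: float = 25.0
    saccade_merge_gap_ms: float = 20.0
    blink_guard_ms: float = 20.0
    excursion_limit_deg: float = 2.0
    excursion_mode: str = "x"  # or "euclidean"
    capture_radius_deg: float = 1.5
    qc_enabled: bool = True


@dataclass
class MetricsConfig:
    baseline_window_ms: list[float] = field(default_factory=lambda: [-300.0, 0.0])
    # 40 ms: band-limited velocity noise produces >20-ms supra-threshold
    # excursions near the onset foot, biasing onset early and the initial
    # acceleration window low
    sustain_ms: float = 40.0
    onset_threshold_floor: float = 0.05
    accel_window_ms: float = 100.0
    steady_window_ms: list[float] = field(default_factory=lambda: [300.0, 500.0])
    onset_mode: str = "averaged"  # detect on averaged traces ("per_trial" option)
    min_trace_count: int = 1


@dataclass
class StatsConfig:
    gg_correction: bool = False
    alpha: float = 0.05


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "results"
    write_traces: bool = False
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    session: SessionConfig = field(default_factory=SessionConfig)
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for name, sub_cls in (
            ("geometry", GeometryConfig),
            ("session", SessionConfig),
            ("simulator", SimulatorConfig),
            ("preprocess", PreprocessConfig),
            ("metrics", MetricsConfig),
            ("stats", StatsConfig),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub_cls(**kwargs[name])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        """Stable short hash of the full configuration (for run logs)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
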
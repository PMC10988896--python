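"""Acquisition method configuration: DIA cycle parameters, trigger
parameters and instrument settings, with YAML round-trip.

Defaults mirror a 2-plex internal-standard-triggered hybrid PRM/DIA method on
a high-field Orbitrap: 400-1210 Th precursor range tiled by 15 Th DIA windows
(one MS1 every 18 MS2 scans), 1.4 Th multiplexed-PRM windows, 10 ppm trigger
mass tolerance, a 5e4-charge MS1 trigger threshold (the lower of the two
thresholds such methods run with; at this model's MS1 charge scale a
100 fmol reference apexes near 1e5-3e5 charges) and 5 s dynamic exclusion.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["TriggerConfig", "MethodConfig"]


@dataclass
class TriggerConfig:
    """Real-time trigger, validation and multiplexed-PRM settings."""

    ppm_tol: float = 10.0
    intensity_threshold: float = 5e4
    min_validated_fragments: int = 4
    max_injection_ms: float = 116.0
    agc_target: float = 1e6
    exclusion_s: float = 5.0
    multiplex_count: int = 2
    msxprm_isolation_width: float = 1.4
    msxprm_resolution: int = 30000
    validation_resolution: int = 7500
    validation_max_injection_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.ppm_tol <= 0:
            raise ValueError("ppm_tol must be > 0")
        if self.multiplex_count != 2:
            raise ValueError("only 2-plex (heavy/light) MSxPRM is supported")
        if not 0 < self.exclusion_s:
            raise ValueError("exclusion_s must be > 0")


@dataclass
class MethodConfig:
    """Full acquisition method for one run."""

    scan_range: tuple[float, float] = (400.0, 1210.0)
    window_width: float = 15.0
    ms2_per_ms1: int = 18
    ms1_resolution: int = 60000
    ms2_resolution: int = 30000
    ms1_agc: float = 3e6
    ms2_agc: float = 1e6
    ms1_max_injection_ms: float = 100.0
    ms2_max_injection_ms: float = 54.0
    run_length_s: float = 7200.0
    trigger: TriggerConfig = field(default_factory=TriggerConfig)

    def __post_init__(self) -> None:
        if isinstance(self.trigger, dict):
            self.trigger = TriggerConfig(**self.trigger)
        self.scan_range = tuple(self.scan_range)
        if self.scan_range[1] <= self.scan_range[0]:
            raise ValueError("scan_range must be (low, high) with high > low")
        if self.window_width <= 0:
            raise ValueError("window_width must be > 0")
        if self.ms2_per_ms1 < 1:
            raise ValueError("ms2_per_ms1 must be >= 1")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["scan_range"] = list(self.scan_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MethodConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)
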
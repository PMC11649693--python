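"""Framework configuration: every tunable constant in one serialisable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigurationError


@dataclass
class FrameworkConfig:
    """All framework constants with their defaults.

    Units are SI throughout; time-based parameters are seconds, never
    sample counts, so the framework is sample-rate agnostic.

    Attributes
    ----------
    sample_rate : Hz, default grid for generated/converted signals.
    detection_ratio : scaling of the personalised global extrema that an
        extremum must exceed to count as an anomaly (sensitivity knob).
    outlier_factor_quartile, outlier_factor_max_mean : the ``c`` factors
        of the two outlier identifiers.
    bin_width_alpha / bin_width_omega : histogram bin widths of the
        extrema distribution monitor (rad/s^2, rad/s).
    monitor_limit_alpha / monitor_limit_omega : magnitude range covered
        by the monitored bins.
    clamp_alpha / clamp_omega : noise bands; an irrelevance bound never
        lies inside +-clamp.
    step_tolerance : relative tolerance used whenever a spacing has to
        match the step period (and for spacing similarity checks).
    step2_offset : seconds added on both sides of a window before the
        frequency-content analysis.
    correlation_interval : half-width (s) of the centred interval within
        which angular-velocity and -acceleration outliers count as
        time-correlated.
    type_interval_cap : upper limit (s) of the initial interval analysed
        for perturbation typing.
    boundary_offset_periods : step periods added before/after a window
        in the boundary-outlier analysis and used for the preceding-task
        interval.
    forward_pitch_positive : sign convention; True means a positive
        omega_y is anterior (forward) pitch.
    """

    sample_rate: float = 100.0
    detection_ratio: float = 1.15
    outlier_factor_quartile: float = 1.5
    outlier_factor_max_mean: float = 1.5
    bin_width_alpha: float = 1.0
    bin_width_omega: float = 0.05
    monitor_limit_alpha: float = 5.0
    monitor_limit_omega: float = 0.25
    clamp_alpha: float = 2.0
    clamp_omega: float = 0.1
    step_tolerance: float = 0.10
    step2_offset: float = 1.25
    correlation_interval: float = 0.15
    type_interval_cap: float = 0.25
    boundary_offset_periods: float = 4.0
    forward_pitch_positive: bool = True
    max_calibration_iterations: int = 20
    min_baseline_steps: int = 10
    autocorr_max_lag: float = 2.5
    smoothing_enabled: bool = False
    smoothing_cutoff_hz: float = 20.0
    running_amp_factor: float = 4.1
    running_period_factor: float = 0.72
    standing_amp_reference: float = 1.0
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "FrameworkConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "FrameworkConfig":
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        data = yaml.safe_load(p.read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {p} does not hold a mapping")
        return cls.from_dict(data)
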
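"""Personalised-threshold calibration from baseline walking trials.

The framework scales all of its detection rules by per-subject
thresholds extracted from a few unperturbed walking trials recorded at a
target speed of about 1.4 m/s: the averaged step frequency, and the
global and averaged-local extrema of the transverse-axis angular
velocity and acceleration.

The touchdown of each foot induces a recurring local maximum in the
angular acceleration signal; its repetition rate defines the step
frequency (the autocorrelation peak corresponds to the interval between
successive touchdowns, so 60 x f is comparable to a cadence in
steps/min).  The averaged-local thresholds are computed only over
*relevant* maxima — those whose spacing is consistent with the step
period — after a preliminary exclusion of noise-dominated low-magnitude
extrema by the distribution monitor.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .config import FrameworkConfig
from .errors import CalibrationError, InvalidInputError
from .kinematics import KinematicsSeries
from .subroutines import (
    ExtremumPoint,
    HistogramSpec,
    autocorrelation,
    distribution_monitor,
    first_dominant_period,
    extrema_summary,
    local_extrema,
)


@dataclass
class BaselineTrial:
    """An unperturbed walking recording used for calibration."""

    kin: KinematicsSeries
    subject_id: str = "anonymous"
    target_speed: float = 1.4  # m/s
    ground_truth: Optional[dict] = None


@dataclass
class SignalThresholds:
    """Per-signal calibration results (signal units)."""

    global_max: float
    global_min: float
    avg_local_max: float
    avg_local_min: float
    irrelevance_max: Optional[float] = None
    irrelevance_min: Optional[float] = None


@dataclass
class PersonalisedThresholds:
    """Per-subject calibration: step frequency plus per-signal extrema."""

    step_frequency: float  # Hz
    omega_y: SignalThresholds
    alpha_y: SignalThresholds
    subject_id: str = "anonymous"
    n_trials: int = 0

    @property
    def step_period(self) -> float:
        return 1.0 / self.step_frequency

    @property
    def steps_per_minute(self) -> float:
        return 60.0 * self.step_frequency

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PersonalisedThresholds":
        d = dict(data)
        d["omega_y"] = SignalThresholds(**d["omega_y"])
        d["alpha_y"] = SignalThresholds(**d["alpha_y"])
        d.pop("step_period", None)
        d.pop("steps_per_minute", None)
        return cls(**d)


def estimate_step_frequency(
    baseline: BaselineTrial, config: Optional[FrameworkConfig] = None
) -> float:
    """Averaged step frequency (Hz) from the angular-acceleration autocorrelation.

    The reciprocal of the lag of the dominant autocorrelation peak of
    alpha_y.  Multiply by 60 for a steps/min figure comparable to
    cadence tables.
    """
    cfg = config or FrameworkConfig()
    kin = baseline.kin
    ac = autocorrelation(kin.alpha_y, kin.dt, cfg.autocorr_max_lag)
    lag = first_dominant_period(ac)
    if lag is None:
        raise CalibrationError(
            "no autocorrelation peak found in baseline angular acceleration; "
            "the trial may be too short or aperiodic"
        )
    return 1.0 / lag


def _gaps_match_step(
    times: np.ndarray, step_period: float, tolerance: float, min_fraction: float = 0.9
) -> bool:
    """True when successive gaps are whole numbers of step periods.

    A gap of about n periods (n >= 1) is accepted so that a single
    missed touchdown does not break the match.  A small share of
    non-matching gaps (below ``1 - min_fraction``) is tolerated: an
    isolated noise intruder breaks only its two adjacent gaps, whereas
    systematic clutter between touchdowns breaks half of them and still
    fails the test.
    """
    if len(times) < 2:
        return False
    gaps = np.diff(np.sort(times))
    n = np.maximum(np.round(gaps / step_period), 1.0)
    good = np.abs(gaps - n * step_period) <= tolerance * n * step_period
    return bool(good.mean() >= min_fraction)


def select_relevant_maxima(
    maxima: Sequence[ExtremumPoint],
    step_period: float,
    bin_width: float,
    start_cutoff: float,
    tolerance: float,
    max_iterations: int,
) -> List[ExtremumPoint]:
    """Iteratively raise the magnitude cutoff until the surviving maxima
    are spaced like steps.

    Each iteration raises the exclusion cutoff by one histogram bin
    width; the routine stops when every gap between surviving adjacent
    maxima matches the step period (or, for an occasional missed
    touchdown, a whole multiple of it) within ``tolerance``.
    """
    cutoff = start_cutoff
    for _ in range(max_iterations + 1):
        kept = [m for m in maxima if m.value > cutoff]
        times = np.array([m.time for m in kept])
        if _gaps_match_step(times, step_period, tolerance):
            return kept
        cutoff += bin_width
    raise CalibrationError(
        f"relevant-maxima selection did not converge within "
        f"{max_iterations} iterations (last cutoff {cutoff:.3g}); "
        "baseline may lack touchdown-induced maxima at the step period"
    )


def _calibrate_signal(
    kin_t: np.ndarray,
    values: np.ndarray,
    step_period: float,
    bin_width: float,
    limit: float,
    clamp: float,
    cfg: FrameworkConfig,
    periodic_maxima: bool = True,
) -> SignalThresholds:
    maxima, minima = local_extrema(values, kin_t)
    if not maxima or not minima:
        raise CalibrationError("baseline signal lacks maxima or minima")
    spec = HistogramSpec(bin_width=bin_width, limit=limit, clamp=clamp)
    irr_max = distribution_monitor(maxima, spec, "max", c=cfg.outlier_factor_quartile)
    irr_min = distribution_monitor(minima, spec, "min", c=cfg.outlier_factor_quartile)

    start_cutoff = irr_max if irr_max is not None else 0.0
    if periodic_maxima:
        # Touchdown-induced maxima: select by spacing consistency with
        # the step period.
        relevant_max = select_relevant_maxima(
            maxima,
            step_period,
            bin_width,
            start_cutoff,
            cfg.step_tolerance,
            cfg.max_calibration_iterations,
        )
    else:
        # Maxima unrelated to sharp gait events (angular velocity):
        # two cutoff iterations, mirroring the minima refinement.
        cutoff_max = start_cutoff + 2.0 * bin_width
        relevant_max = [m for m in maxima if m.value > cutoff_max]
        if not relevant_max:
            raise CalibrationError(
                "no baseline maxima survive the two-iteration refinement"
            )
    # Minima are unrelated to periodic gait events: exactly two cutoff
    # iterations below the irrelevance bound, no spacing condition.
    cutoff_min = (irr_min if irr_min is not None else 0.0) - 2.0 * bin_width
    relevant_min = [m for m in minima if m.value < cutoff_min]
    if not relevant_min:
        raise CalibrationError(
            "no baseline minima survive the two-iteration refinement; "
            "signal amplitudes may be below the noise clamp"
        )
    summary = extrema_summary(relevant_max, relevant_min)
    # Global extrema come from the full identifier output.
    all_max = max(m.value for m in maxima)
    all_min = min(m.value for m in minima)
    return SignalThresholds(
        global_max=all_max,
        global_min=all_min,
        avg_local_max=summary.avg_local_max,
        avg_local_min=summary.avg_local_min,
        irrelevance_max=irr_max,
        irrelevance_min=irr_min,
    )


def _validate_baseline(trial: BaselineTrial, step_frequency: float, cfg: FrameworkConfig) -> None:
    n_steps = trial.kin.duration * step_frequency
    if n_steps < cfg.min_baseline_steps:
        raise InvalidInputError(
            f"baseline trial holds about {n_steps:.1f} steps of signal; "
            f"at least {cfg.min_baseline_steps} are required"
        )


def calibrate(
    baselines: Sequence[BaselineTrial], config: Optional[FrameworkConfig] = None
) -> PersonalisedThresholds:
    """Calibrate personalised thresholds from one or more baseline trials.

    Deterministic given the trials and configuration.  Per trial the
    step frequency is estimated, irrelevant magnitudes are excluded via
    the distribution monitor, relevant maxima are selected iteratively
    (minima with exactly two refinement iterations), and the surviving
    extrema are summarised; thresholds are then averaged arithmetically
    across trials.
    """
    cfg = config or FrameworkConfig()
    if not baselines:
        raise InvalidInputError("at least one baseline trial is required")
    per_trial: List[dict] = []
    for trial in baselines:
        freq = estimate_step_frequency(trial, cfg)
        _validate_baseline(trial, freq, cfg)
        period = 1.0 / freq
        alpha = _calibrate_signal(
            trial.kin.t,
            trial.kin.alpha_y,
            period,
            cfg.bin_width_alpha,
            cfg.monitor_limit_alpha,
            cfg.clamp_alpha,
            cfg,
        )
        omega = _calibrate_signal(
            trial.kin.t,
            trial.kin.omega_y,
            period,
            cfg.bin_width_omega,
            cfg.monitor_limit_omega,
            cfg.clamp_omega,
            cfg,
            periodic_maxima=False,
        )
        per_trial.append({"freq": freq, "alpha": alpha, "omega": omega})

    def _avg(signal: str, fieldname: str) -> float:
        return float(np.mean([getattr(d[signal], fieldname) for d in per_trial]))

    def _avg_opt(signal: str, fieldname: str) -> Optional[float]:
        vals = [getattr(d[signal], fieldname) for d in per_trial]
        present = [v for v in vals if v is not None]
        return float(np.mean(present)) if present else None

    def _signal(signal: str) -> SignalThresholds:
        return SignalThresholds(
            global_max=_avg(signal, "global_max"),
            global_min=_avg(signal, "global_min"),
            avg_local_max=_avg(signal, "avg_local_max"),
            avg_local_min=_avg(signal, "avg_local_min"),
            irrelevance_max=_avg_opt(signal, "irrelevance_max"),
            irrelevance_min=_avg_opt(signal, "irrelevance_min"),
        )

    return PersonalisedThresholds(
        step_frequency=float(np.mean([d["freq"] for d in per_trial])),
        omega_y=_signal("omega"),
        alpha_y=_signal("alpha"),
        subject_id=baselines[0].subject_id,
        n_trials=len(baselines),
    )
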
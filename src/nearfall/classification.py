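"""Balance-recovery versus ADL classification of observation windows.

Detecting an observation window is only the *necessary* condition for a
near-fall: running or picking up an object also drives trunk kinematics
beyond the personalised thresholds.  A three-step analysis of each
window supplies the *sufficient* condition:

1. Periodicity versus correlated outliers inside the window.  Three or
   more touchdown-type angular-acceleration maxima at a mutually similar
   spacing indicate a consciously performed periodic activity (ADL).  A
   transient spacing shorter than the step period caused by a
   maximum-versus-mean outlier in the angular acceleration that is
   time-correlated with an angular-velocity outlier indicates a balance
   recovery response.
2. Frequency content.  The autocorrelation of the window (extended by a
   fixed offset) is screened for coefficient peaks with outlier
   character; a flagged lag shorter than the step period that is not
   part of a repeating (harmonic) pattern marks transient frequency
   content — a recovery response.
3. Boundary outliers.  The window extended by several step periods on
   both sides is screened for a time-correlated pair of outliers in the
   two signals; absence of such a pair defaults the window to ADL.

A recovery window is then attributed to the locomotor task preceding its
onset (standing / walking / running) and typed by the sign of the
dominant initial angular-velocity extremum: under the forward-pitch-
positive convention, a forward rotation during walking is a trip and a
backward one a slip; during standing they are anterior and posterior
loss of balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np

from .config import FrameworkConfig
from .errors import InsufficientDataError, UnclassifiableTypeError
from .kinematics import KinematicsSeries
from .subroutines import (
    ExtremumPoint,
    autocorrelation,
    dominant_periods,
    first_dominant_period,
    local_extrema,
    outlier_max_vs_mean,
    outlier_quartile,
)
from .thresholds import PersonalisedThresholds, select_relevant_maxima
from .window_detection import ObservationWindow, detect_windows

Verdict = Literal["ADL", "recovery", "undecided"]
Task = Literal["standing", "walking", "running"]
PerturbationType = Literal["trip", "slip", "anterior_loss", "posterior_loss", "none"]


@dataclass
class DecisionTrace:
    """Which step fired and why, for one observation window."""

    step: int
    condition: Literal[
        "periodic_ADL",
        "correlated_outliers",
        "transient_frequency",
        "boundary_outliers",
        "default_ADL",
    ]
    evidence: dict = field(default_factory=dict)


@dataclass
class TaskReference:
    """Reference features (averaged local alpha_y maximum, dominant
    period) per locomotor task, used for preceding-task attribution.

    The walking entry equals the calibrated thresholds; standing and
    running defaults are scaled from it (configurable, and replaceable
    by measured per-task references).
    """

    amplitudes: dict  # task -> rad/s^2
    periods: dict     # task -> s

    @classmethod
    def from_thresholds(
        cls, th: PersonalisedThresholds, config: Optional[FrameworkConfig] = None
    ) -> "TaskReference":
        cfg = config or FrameworkConfig()
        walk_amp = th.alpha_y.avg_local_max
        period = th.step_period
        return cls(
            amplitudes={
                "standing": cfg.standing_amp_reference,
                "walking": walk_amp,
                "running": walk_amp * cfg.running_amp_factor,
            },
            periods={
                "standing": period,
                "walking": period,
                "running": period * cfg.running_period_factor,
            },
        )


@dataclass
class PerturbationCall:
    """Final verdict for one observation window."""

    is_recovery: bool
    type: PerturbationType
    preceding: Optional[Task]
    trace: DecisionTrace
    window: ObservationWindow
    direction: Optional[Literal["anterior", "posterior"]] = None

    def to_dict(self) -> dict:
        return {
            "is_recovery": self.is_recovery,
            "type": self.type,
            "preceding": self.preceding,
            "direction": self.direction,
            "trace": {
                "step": self.trace.step,
                "condition": self.trace.condition,
                "evidence": self.trace.evidence,
            },
            "window": self.window.to_dict(),
        }


def _signed_sets(
    extrema: Sequence[ExtremumPoint],
) -> List[List[Tuple[float, float]]]:
    """Split extrema into the sign-pure (value, time) sets the
    maximum-versus-mean test accepts."""
    pos = [(e.value, e.time) for e in extrema if e.value >= 0]
    neg = [(e.value, e.time) for e in extrema if e.value < 0]
    return [s for s in (pos, neg) if len(s) >= 2]


def _supra_clamp(
    extrema: Sequence[ExtremumPoint], clamp: float
) -> List[ExtremumPoint]:
    """Extrema of supra-noise magnitude.

    Magnitudes inside the noise clamp are attributable to sensor noise;
    admitting them to the maximum-versus-mean test would dilute the mean
    and make ordinary gait extrema look like outliers.
    """
    return [e for e in extrema if abs(e.value) >= clamp]


def _method2_outliers(
    extrema: Sequence[ExtremumPoint],
    c: float,
    clamp: float = 0.0,
    floor_max: Optional[float] = None,
    floor_min: Optional[float] = None,
    fallback: bool = True,
) -> List[Tuple[float, float]]:
    """All (value, time) outliers found by the maximum-versus-mean test,
    applied separately to the maxima-like and minima-like subsets.

    Each subset holds the *relevant* extrema — those reaching at least
    the personalised averaged-local threshold, i.e. of typical
    touchdown magnitude; smaller extrema are ordinary locomotor or
    noise content by the calibration's own definition and would only
    dilute the mean.  A context with fewer than two such extrema
    (quiet stance) falls back to the supra-clamp set, against which an
    isolated anomaly stands out directly.
    """
    sc = _supra_clamp(extrema, clamp)
    pos = [(e.value, e.time) for e in sc if e.value >= 0]
    neg = [(e.value, e.time) for e in sc if e.value < 0]
    if floor_max is not None:
        relevant = [p for p in pos if p[0] >= floor_max]
        pos = relevant if (len(relevant) >= 2 or not fallback) else pos
    if floor_min is not None:
        relevant = [p for p in neg if p[0] <= floor_min]
        neg = relevant if (len(relevant) >= 2 or not fallback) else neg
    out = []
    for subset in (pos, neg):
        if len(subset) < 2:
            continue
        is_out, pt = outlier_max_vs_mean(subset, c=c)
        if is_out:
            out.append(pt)
    return out


def step1_periodicity_vs_outliers(
    window: ObservationWindow,
    kin: KinematicsSeries,
    th: PersonalisedThresholds,
    config: Optional[FrameworkConfig] = None,
) -> Tuple[Verdict, DecisionTrace]:
    """Step 1: periodic repetitions versus correlated outlier pairs."""
    cfg = config or FrameworkConfig()
    seg = kin.segment(window.onset, window.offset)
    a_max, a_min = local_extrema(seg.alpha_y, seg.t)
    w_max, w_min = local_extrema(seg.omega_y, seg.t)

    touchdown = sorted(
        (m for m in a_max if m.value >= cfg.clamp_alpha), key=lambda m: m.time
    )
    td_times = np.array([m.time for m in touchdown])

    # ADL condition: three or more touchdown-type maxima repeating at
    # the window's own dominant period, with consistent magnitudes.
    # The touchdown-type maxima are isolated the same way calibration
    # isolates them — by raising a magnitude cutoff until the surviving
    # maxima are spaced like the dominant period found by
    # autocorrelation.  A decaying recovery oscillation can mimic the
    # spacing regularity but not the magnitude consistency, so a
    # maximum-versus-mean outlier among the candidate repetitions
    # vetoes the periodic verdict.  Checked ahead of the outlier pair:
    # an intact periodic pattern spanning the window is direct evidence
    # of a consciously performed activity.
    repetitions: List[ExtremumPoint] = []
    if len(touchdown) >= 3:
        try:
            ac = autocorrelation(
                seg.alpha_y, seg.dt, min(cfg.autocorr_max_lag, seg.duration * 0.9)
            )
            p_window = first_dominant_period(ac)
        except Exception:
            p_window = None
        if p_window is not None:
            # the cutoff scan must span the window's own magnitude
            # range within the iteration cap, so the step grows with it
            top = max(m.value for m in touchdown)
            step = max(
                cfg.bin_width_alpha,
                (top - cfg.clamp_alpha) / cfg.max_calibration_iterations,
            )
            try:
                repetitions = select_relevant_maxima(
                    touchdown,
                    p_window,
                    step,
                    cfg.clamp_alpha,
                    cfg.step_tolerance,
                    cfg.max_calibration_iterations,
                )
            except Exception:
                repetitions = []
    if len(repetitions) >= 3:
        rep_gaps = np.diff(sorted(m.time for m in repetitions))
        magnitudes_ok = not outlier_max_vs_mean(
            [(m.value, m.time) for m in repetitions], c=cfg.outlier_factor_max_mean
        )[0]
        if magnitudes_ok:
            return "ADL", DecisionTrace(
                step=1,
                condition="periodic_ADL",
                evidence={
                    "n_repetitions": len(repetitions),
                    "median_spacing": float(np.median(rep_gaps)),
                },
            )

    # Recovery condition: an angular-acceleration outlier producing a
    # transient frequency change — spacing around the outlier breaking
    # the window's own repetition rhythm — time-correlated with an
    # angular-velocity outlier.
    a_outliers = _method2_outliers(
        a_max + a_min,
        cfg.outlier_factor_max_mean,
        cfg.clamp_alpha,
        floor_max=th.alpha_y.avg_local_max,
        floor_min=th.alpha_y.avg_local_min,
        fallback=False,
    )
    w_outliers = _method2_outliers(
        w_max + w_min,
        cfg.outlier_factor_max_mean,
        cfg.clamp_omega,
        floor_max=th.omega_y.avg_local_max,
        floor_min=th.omega_y.avg_local_min,
        fallback=False,
    )
    gaps_all = np.diff(td_times) if len(td_times) >= 2 else np.array([])
    rhythm = float(np.median(gaps_all)) if len(gaps_all) >= 2 else None
    for a_val, a_time in a_outliers:
        neighbour_gaps = np.abs(td_times[td_times != a_time] - a_time)
        if len(neighbour_gaps) == 0 or rhythm is None:
            transient = True  # isolated anomaly: nothing rhythmic around it
        else:
            gap = float(neighbour_gaps.min())
            # a periodic repetition sits one rhythm interval from its
            # neighbours; a recovery oscillation packs extrema much
            # closer, and always inside one step period
            transient = gap < 0.5 * rhythm and gap < th.step_period
        if not transient:
            continue
        for w_val, w_time in w_outliers:
            if abs(w_time - a_time) <= cfg.correlation_interval:
                return "recovery", DecisionTrace(
                    step=1,
                    condition="correlated_outliers",
                    evidence={
                        "alpha_outlier": {"value": a_val, "time": a_time},
                        "omega_outlier": {"value": w_val, "time": w_time},
                    },
                )
    return "undecided", DecisionTrace(step=1, condition="default_ADL", evidence={})


def _transient_short_lags(
    values: np.ndarray,
    dt: float,
    max_lag: float,
    step_period: float,
    c: float,
    tol: float,
) -> List[float]:
    """Flagged autocorrelation peak lags that are shorter than the step
    period and not part of a repeating harmonic pattern."""
    ac = autocorrelation(values, dt, max_lag)
    peaks = dominant_periods(ac)
    if len(peaks) < 4:
        return []
    r_vals = np.array([r for _, r in peaks])
    # High-side flags only: a peak is evidence of *present* frequency
    # content when its coefficient stands out above the others.
    q1, q3 = np.quantile(r_vals, [0.25, 0.75])
    mask = outlier_quartile(r_vals, c=c) & (r_vals > q3)
    flagged = [peaks[i][0] for i in range(len(peaks)) if mask[i]]
    short = [lag for lag in flagged if lag < step_period]
    if not short:
        return []
    all_lags = np.array([lag for lag, _ in peaks])
    transient = []
    for lag in short:
        repeated = False
        for m in range(2, int(np.floor(all_lags.max() / lag)) + 1):
            if np.any(np.abs(all_lags - m * lag) <= tol * m * lag):
                repeated = True
                break
        if not repeated:
            transient.append(lag)
    return transient


def step2_frequency_content(
    window: ObservationWindow,
    kin: KinematicsSeries,
    th: PersonalisedThresholds,
    config: Optional[FrameworkConfig] = None,
) -> Tuple[Verdict, DecisionTrace]:
    """Step 2: transient frequency content above the step frequency."""
    cfg = config or FrameworkConfig()
    t0 = max(window.onset - cfg.step2_offset, float(kin.t[0]))
    t1 = min(window.offset + cfg.step2_offset, float(kin.t[-1]))
    seg = kin.segment(t0, t1)
    max_lag = min(cfg.autocorr_max_lag, seg.duration * 0.9)
    for name, values in (("alpha_y", seg.alpha_y), ("omega_y", seg.omega_y)):
        lags = _transient_short_lags(
            values,
            seg.dt,
            max_lag,
            th.step_period,
            cfg.outlier_factor_quartile,
            cfg.step_tolerance,
        )
        if lags:
            return "recovery", DecisionTrace(
                step=2,
                condition="transient_frequency",
                evidence={"signal": name, "transient_lags": lags},
            )
    return "undecided", DecisionTrace(step=2, condition="default_ADL", evidence={})


def step3_boundary_outliers(
    window: ObservationWindow,
    kin: KinematicsSeries,
    th: PersonalisedThresholds,
    config: Optional[FrameworkConfig] = None,
) -> Tuple[Verdict, DecisionTrace]:
    """Step 3: correlated outlier pair in the boundary-extended window."""
    cfg = config or FrameworkConfig()
    pad = cfg.boundary_offset_periods * th.step_period
    t0 = max(window.onset - pad, float(kin.t[0]))
    t1 = min(window.offset + pad, float(kin.t[-1]))
    seg = kin.segment(t0, t1)
    a_max, a_min = local_extrema(seg.alpha_y, seg.t)
    w_max, w_min = local_extrema(seg.omega_y, seg.t)
    a_outliers = _method2_outliers(
        a_max + a_min,
        cfg.outlier_factor_max_mean,
        cfg.clamp_alpha,
        floor_max=th.alpha_y.avg_local_max,
        floor_min=th.alpha_y.avg_local_min,
    )
    w_outliers = _method2_outliers(
        w_max + w_min,
        cfg.outlier_factor_max_mean,
        cfg.clamp_omega,
        floor_max=th.omega_y.avg_local_max,
        floor_min=th.omega_y.avg_local_min,
    )
    for a_val, a_time in a_outliers:
        for w_val, w_time in w_outliers:
            if abs(w_time - a_time) <= cfg.correlation_interval:
                return "recovery", DecisionTrace(
                    step=3,
                    condition="boundary_outliers",
                    evidence={
                        "alpha_outlier": {"value": a_val, "time": a_time},
                        "omega_outlier": {"value": w_val, "time": w_time},
                    },
                )
    return "ADL", DecisionTrace(step=3, condition="default_ADL", evidence={})


def classify_preceding_task(
    kin: KinematicsSeries,
    onset: float,
    th: PersonalisedThresholds,
    refs: Optional[TaskReference] = None,
    config: Optional[FrameworkConfig] = None,
) -> Task:
    """Attribute the interval before a window onset to standing, walking
    or running.

    Features over the four step periods preceding the onset: the mean of
    the relevant angular-acceleration maxima and the dominant period
    from autocorrelation.  The reference task with the least summed
    relative deviation wins; an interval with no maxima above the noise
    clamp is standing by the amplitude floor rule; distance ties resolve
    to walking.
    """
    cfg = config or FrameworkConfig()
    references = refs or TaskReference.from_thresholds(th, cfg)
    t0 = max(onset - cfg.boundary_offset_periods * th.step_period, float(kin.t[0]))
    t1 = onset - kin.dt
    try:
        seg = kin.segment(t0, t1)
    except Exception:
        return "standing"
    a_max, _ = local_extrema(seg.alpha_y, seg.t)
    above = [m for m in a_max if m.value >= cfg.clamp_alpha]
    if len(above) < 2:
        # Amplitude floor: locomotion shows repeated supra-noise maxima;
        # at most one isolated spike still reads as quiet stance.
        return "standing"
    try:
        ac = autocorrelation(seg.alpha_y, seg.dt, min(cfg.autocorr_max_lag, seg.duration * 0.9))
        period = first_dominant_period(ac)
    except Exception:
        period = None
    if period is None:
        return "standing"
    try:
        relevant = select_relevant_maxima(
            above,
            period,
            cfg.bin_width_alpha,
            cfg.clamp_alpha,
            cfg.step_tolerance,
            cfg.max_calibration_iterations,
        )
    except Exception:
        relevant = above
    amp = float(np.mean([m.value for m in relevant]))

    best: Task = "walking"
    best_dev = np.inf
    for task in ("walking", "running", "standing"):  # walking first wins ties
        ref_amp = references.amplitudes[task]
        ref_per = references.periods[task]
        dev = abs(amp - ref_amp) / abs(ref_amp) + abs(period - ref_per) / abs(ref_per)
        if dev < best_dev - 1e-12:
            best_dev = dev
            best = task
    return best


def classify_perturbation_type(
    kin: KinematicsSeries,
    window: ObservationWindow,
    preceding: Task,
    config: Optional[FrameworkConfig] = None,
) -> Tuple[PerturbationType, Literal["anterior", "posterior"]]:
    """Type a recovery window from the sign of the dominant initial
    angular-velocity extremum.

    The initial interval is half the window duration capped at a fixed
    limit.  Under the forward-pitch-positive convention: positive during
    walking = trip, negative = slip; positive during standing = anterior
    loss of balance, negative = posterior.  A running antecedent reports
    the direction only (type ``none``).
    """
    cfg = config or FrameworkConfig()
    horizon = min(window.duration / 2.0, cfg.type_interval_cap)
    seg = kin.segment(window.onset, window.onset + max(horizon, 2 * kin.dt))
    w_max, w_min = local_extrema(seg.omega_y, seg.t)
    extrema = w_max + w_min
    if not extrema:
        raise UnclassifiableTypeError(
            "no angular-velocity extremum in the initial interval"
        )
    dominant = max(extrema, key=lambda e: abs(e.value))
    positive = dominant.value >= 0
    anterior = positive if cfg.forward_pitch_positive else not positive
    direction = "anterior" if anterior else "posterior"
    if preceding == "walking":
        return ("trip" if anterior else "slip"), direction
    if preceding == "standing":
        return ("anterior_loss" if anterior else "posterior_loss"), direction
    return "none", direction


def classify_window(
    window: ObservationWindow,
    kin: KinematicsSeries,
    th: PersonalisedThresholds,
    refs: Optional[TaskReference] = None,
    config: Optional[FrameworkConfig] = None,
) -> PerturbationCall:
    """Run the three-step analysis on one window and, for recoveries,
    attribute the preceding task and perturbation type."""
    cfg = config or FrameworkConfig()
    verdict, trace = step1_periodicity_vs_outliers(window, kin, th, cfg)
    if verdict == "undecided":
        verdict, trace = step2_frequency_content(window, kin, th, cfg)
    if verdict == "undecided":
        verdict, trace = step3_boundary_outliers(window, kin, th, cfg)
    if verdict != "recovery":
        return PerturbationCall(
            is_recovery=False, type="none", preceding=None, trace=trace, window=window
        )
    preceding = classify_preceding_task(kin, window.onset, th, refs, cfg)
    try:
        ptype, direction = classify_perturbation_type(kin, window, preceding, cfg)
    except UnclassifiableTypeError:
        ptype, direction = "none", None
    return PerturbationCall(
        is_recovery=True,
        type=ptype,
        preceding=preceding,
        trace=trace,
        window=window,
        direction=direction,
    )


def classify_trial(
    kin: KinematicsSeries,
    th: PersonalisedThresholds,
    refs: Optional[TaskReference] = None,
    config: Optional[FrameworkConfig] = None,
) -> List[PerturbationCall]:
    """Full per-trial pipeline: detect windows, then classify each.

    Returns one call per surviving window in temporal order; an
    unperturbed trial with no anomalies yields an empty list.
    """
    cfg = config or FrameworkConfig()
    windows = detect_windows(kin, th, config=cfg)
    return [classify_window(w, kin, th, refs, cfg) for w in windows]
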
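"""Observation-window detection: the necessary condition for a near-fall.

A candidate anomaly interval ("observation window") is flagged when
*both* trunk kinematic signals contain extrema exceeding a scaled
personalised global threshold.  Angular-velocity anomalies are clustered
into temporary windows, extended by half a step period, confirmed by a
coincident angular-acceleration anomaly, and finally refined to zero
crossings of the angular-acceleration signal with a quiet-period check
on the offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import FrameworkConfig
from .errors import ConfigurationError
from .kinematics import KinematicsSeries
from .subroutines import ExtremumPoint, local_extrema
from .thresholds import PersonalisedThresholds


@dataclass
class ObservationWindow:
    """A candidate anomaly interval with its detection provenance."""

    onset: float
    offset: float
    temporary_bounds: Tuple[float, float]
    extended_bounds: Tuple[float, float]
    omega_extrema: List[ExtremumPoint] = field(default_factory=list)
    alpha_extrema: List[ExtremumPoint] = field(default_factory=list)
    truncated_onset: bool = False
    truncated_offset: bool = False

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def to_dict(self) -> dict:
        return {
            "onset": self.onset,
            "offset": self.offset,
            "temporary_bounds": list(self.temporary_bounds),
            "extended_bounds": list(self.extended_bounds),
            "truncated_onset": self.truncated_onset,
            "truncated_offset": self.truncated_offset,
            "omega_extrema": [
                {"value": e.value, "time": e.time, "kind": e.kind}
                for e in self.omega_extrema
            ],
            "alpha_extrema": [
                {"value": e.value, "time": e.time, "kind": e.kind}
                for e in self.alpha_extrema
            ],
        }


def _exceeding(
    extrema: Sequence[ExtremumPoint], upper: float, lower: float
) -> List[ExtremumPoint]:
    """Extrema strictly beyond the scaled global bounds."""
    return [e for e in extrema if e.value > upper or e.value < lower]


def _cluster_by_gap(
    extrema: Sequence[ExtremumPoint], max_gap: float
) -> List[List[ExtremumPoint]]:
    """Group time-sorted extrema; split where the gap strictly exceeds max_gap."""
    ordered = sorted(extrema, key=lambda e: e.time)
    clusters: List[List[ExtremumPoint]] = []
    for e in ordered:
        if clusters and e.time - clusters[-1][-1].time <= max_gap:
            clusters[-1].append(e)
        else:
            clusters.append([e])
    return clusters


def _zero_crossing_indices(values: np.ndarray) -> np.ndarray:
    """Indices i such that the sign map changes between samples i-1 and i.

    The returned index is the sample *immediately after* the crossing.
    """
    sign = np.where(values >= 0.0, 1, -1)
    return np.nonzero(sign[1:] != sign[:-1])[0] + 1


def refine_onset(
    first_extreme_time: float, kin: KinematicsSeries
) -> Tuple[float, bool]:
    """Onset: the sample immediately after the last angular-acceleration
    zero crossing preceding the first triggering extreme.

    Returns ``(onset, truncated)``; when no crossing precedes the extreme
    the onset clamps to the series start and is flagged truncated.
    """
    crossings = _zero_crossing_indices(kin.alpha_y)
    times = kin.t[crossings]
    before = times[times <= first_extreme_time]
    if len(before) == 0:
        return float(kin.t[0]), True
    return float(before[-1]), False


def refine_offset(
    last_extreme_time: float,
    kin: KinematicsSeries,
    th: PersonalisedThresholds,
    ratio: float,
) -> Tuple[float, bool]:
    """Offset: the angular-acceleration zero crossing after the last
    in-window extreme, accepted only if the following step period stays
    inside the threshold bandwidths.

    The bandwidth is [ratio * global_min, ratio * global_max] per signal
    and the quiet-period test is applied to both signals.  A violating
    extremum re-extends the window and the routine repeats; reaching the
    end of the record truncates the offset.
    """
    period = th.step_period
    crossings = _zero_crossing_indices(kin.alpha_y)
    crossing_times = kin.t[crossings]
    w_max, w_min = local_extrema(kin.omega_y, kin.t)
    a_max, a_min = local_extrema(kin.alpha_y, kin.t)
    all_extrema = sorted(
        [(e.time, e.value, "omega") for e in w_max + w_min]
        + [(e.time, e.value, "alpha") for e in a_max + a_min]
    )
    bands = {
        "omega": (ratio * th.omega_y.global_min, ratio * th.omega_y.global_max),
        "alpha": (ratio * th.alpha_y.global_min, ratio * th.alpha_y.global_max),
    }
    anchor = last_extreme_time
    while True:
        after = crossing_times[crossing_times > anchor + 1e-12]
        if len(after) == 0:
            return float(kin.t[-1]), True
        candidate = float(after[0])
        violator = None
        for t_e, v_e, sig in all_extrema:
            if candidate < t_e <= candidate + period:
                lo, hi = bands[sig]
                if v_e > hi or v_e < lo:
                    violator = t_e
                    break
        if violator is None:
            return candidate, False
        anchor = violator


def detect_windows(
    kin: KinematicsSeries,
    th: Optional[PersonalisedThresholds],
    ratio: Optional[float] = None,
    config: Optional[FrameworkConfig] = None,
) -> List[ObservationWindow]:
    """Detect candidate observation windows in a trunk-kinematics recording.

    Pipeline: (1) angular-velocity extrema beyond ratio x the global
    thresholds are clustered, splitting at gaps longer than one step
    period; (2) each cluster is extended by half a step period on both
    sides; (3) a window survives only if the angular-acceleration signal
    also holds an extremum beyond ratio x its global thresholds inside
    the extended bounds; (4) onset and offset are refined to zero
    crossings with a quiet-period acceptance test, and overlapping
    refined windows are merged.

    Raising ``ratio`` never increases the number of detected windows.
    """
    if th is None:
        raise ConfigurationError("personalised thresholds are required")
    cfg = config or FrameworkConfig()
    r = cfg.detection_ratio if ratio is None else ratio
    period = th.step_period

    w_max, w_min = local_extrema(kin.omega_y, kin.t)
    w_anom = _exceeding(
        w_max + w_min, r * th.omega_y.global_max, r * th.omega_y.global_min
    )
    if not w_anom:
        return []
    a_max, a_min = local_extrema(kin.alpha_y, kin.t)
    a_all = a_max + a_min

    windows: List[ObservationWindow] = []
    for cluster in _cluster_by_gap(w_anom, period):
        t_lo = min(e.time for e in cluster)
        t_hi = max(e.time for e in cluster)
        ext_lo = max(t_lo - period / 2.0, float(kin.t[0]))
        ext_hi = min(t_hi + period / 2.0, float(kin.t[-1]))
        a_anom = [
            e
            for e in _exceeding(
                a_all, r * th.alpha_y.global_max, r * th.alpha_y.global_min
            )
            if ext_lo <= e.time <= ext_hi
        ]
        if not a_anom:
            continue
        trig_times = [e.time for e in cluster] + [e.time for e in a_anom]
        onset, trunc_on = refine_onset(min(trig_times), kin)
        offset, trunc_off = refine_offset(max(trig_times), kin, th, r)
        if offset <= onset:
            offset, trunc_off = float(kin.t[-1]), True
        windows.append(
            ObservationWindow(
                onset=onset,
                offset=offset,
                temporary_bounds=(t_lo, t_hi),
                extended_bounds=(ext_lo, ext_hi),
                omega_extrema=list(cluster),
                alpha_extrema=a_anom,
                truncated_onset=trunc_on,
                truncated_offset=trunc_off,
            )
        )

    windows.sort(key=lambda w: w.onset)
    merged: List[ObservationWindow] = []
    for w in windows:
        if merged and w.onset <= merged[-1].offset:
            prev = merged[-1]
            prev.offset = max(prev.offset, w.offset)
            prev.extended_bounds = (
                min(prev.extended_bounds[0], w.extended_bounds[0]),
                max(prev.extended_bounds[1], w.extended_bounds[1]),
            )
            prev.temporary_bounds = (
                min(prev.temporary_bounds[0], w.temporary_bounds[0]),
                max(prev.temporary_bounds[1], w.temporary_bounds[1]),
            )
            prev.omega_extrema.extend(w.omega_extrema)
            prev.alpha_extrema.extend(w.alpha_extrema)
            prev.truncated_offset = w.truncated_offset
        else:
            merged.append(w)
    return merged
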
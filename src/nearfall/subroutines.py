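"""Stand-alone signal-analysis primitives used throughout the framework.

These are the building blocks every later stage composes:

* :func:`autocorrelation` / :func:`dominant_periods` — periodicity and
  step-frequency estimation without spectral analysis,
* :func:`local_extrema` — segmentation of a signal at zero crossings and
  per-segment extremum extraction,
* :func:`outlier_quartile` / :func:`outlier_max_vs_mean` — the two
  outlier identifiers (quartile fences; maximum-versus-mean ratio),
* :func:`distribution_monitor` — a histogram check over the low-magnitude
  extrema bins that flags noise-dominated magnitude ranges as irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    DegenerateSignalError,
    InsufficientBinsError,
    InsufficientDataError,
    InvalidInputError,
    MissingExtremaError,
)


@dataclass(frozen=True)
class ExtremumPoint:
    """A per-segment extremum: signed value, time, kind and segment index."""

    value: float
    time: float
    kind: Literal["max", "min"]
    segment_index: int


@dataclass(frozen=True)
class ExtremaSummary:
    """Averaged local and global extrema of a signal."""

    avg_local_max: float
    avg_local_min: float
    global_max: float
    global_min: float


@dataclass(frozen=True)
class AutocorrSeries:
    """Autocorrelation coefficients r_k on a grid of lags k = n*dt."""

    lags: np.ndarray
    r: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0]) if len(self.lags) > 1 else 0.0


@dataclass(frozen=True)
class HistogramSpec:
    """Binning used by the extrema distribution monitor.

    ``bin_width`` and ``limit`` are in signal units; ``clamp`` is the
    floor (maxima) / ceiling (minima) applied to a returned irrelevance
    bound, reflecting that magnitudes inside +-clamp are attributable to
    sensor noise rather than trunk motion.
    """

    bin_width: float
    limit: float
    clamp: float

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.limit <= 0:
            raise InvalidInputError("bin_width and limit must be positive")


def autocorrelation(
    values: Sequence[float], dt: float, max_lag: float, demean: bool = False
) -> AutocorrSeries:
    """Raw autocorrelation of a sampled signal.

    c_n = sum_i f[i+n] f[i] over the overlapping samples, normalised by
    c_0.  By default no mean removal and no per-lag renormalisation are
    applied: the trunk signals oscillate around zero and the decaying
    envelope is part of how dominant periods are ranked.  ``demean``
    subtracts the sample mean first (off by default).
    """
    f = np.asarray(values, dtype=float)
    if demean and len(f):
        f = f - f.mean()
    if f.ndim != 1 or len(f) == 0:
        raise InvalidInputError("autocorrelation needs a non-empty 1-D signal")
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    duration = (len(f) - 1) * dt
    if max_lag >= duration:
        max_lag = duration
    n_lags = int(np.floor(max_lag / dt))
    full = np.correlate(f, f, mode="full")
    c = full[len(f) - 1 : len(f) + n_lags]
    if c[0] == 0.0:
        raise DegenerateSignalError("identically zero signal: c_0 = 0")
    return AutocorrSeries(lags=np.arange(n_lags + 1) * dt, r=c / c[0])


def dominant_periods(ac: AutocorrSeries) -> List[Tuple[float, float]]:
    """Local maxima of r_k (lag 0 excluded), sorted by descending r.

    Peaks are located with :func:`local_extrema` applied to the r_k
    series itself, so a monotonically decaying autocorrelation yields an
    empty list.
    """
    maxima, _ = local_extrema(ac.r, ac.lags)
    peaks = [(m.time, m.value) for m in maxima if m.time > 0.0]
    peaks.sort(key=lambda p: -p[1])
    return peaks


def first_dominant_period(
    ac: AutocorrSeries, dominance: float = 0.75
) -> Optional[float]:
    """Lag of the earliest near-maximal autocorrelation peak.

    A periodic signal shows peaks at every multiple of its fundamental
    period, all of comparable height (the envelope decays slowly and
    lag quantisation perturbs their ordering); the fundamental is the
    *earliest* peak whose coefficient reaches ``dominance`` times the
    tallest peak.  Returns ``None`` when there are no peaks.
    """
    peaks = dominant_periods(ac)
    if not peaks:
        return None
    r_max = peaks[0][1]
    candidates = [lag for lag, r in peaks if r >= dominance * r_max]
    return min(candidates)


def _segment_bounds(sign: np.ndarray) -> np.ndarray:
    """Start indices of the sign-pure segments (first segment starts at 0)."""
    change = np.nonzero(sign[1:] != sign[:-1])[0] + 1
    return np.concatenate([[0], change])


def local_extrema(
    values: Sequence[float], times: Optional[Sequence[float]] = None
) -> Tuple[List[ExtremumPoint], List[ExtremumPoint]]:
    """Segment a signal at zero crossings and pick one extremum per segment.

    The timeline is partitioned wherever the sign map (x >= 0 maps to +1,
    x < 0 to -1) changes between adjacent samples.  Every segment is
    sign-pure; each contributes the element of largest absolute value,
    with ties broken by the earliest time.  Non-negative segments feed
    the maxima set, negative segments the minima set.

    Returns ``(maxima, minima)`` as lists of :class:`ExtremumPoint`.
    """
    f = np.asarray(values, dtype=float)
    if f.ndim != 1 or len(f) == 0:
        raise InvalidInputError("local_extrema needs a non-empty 1-D signal")
    t = (
        np.arange(len(f), dtype=float)
        if times is None
        else np.asarray(times, dtype=float)
    )
    if len(t) != len(f):
        raise InvalidInputError("times and values must have equal length")
    sign = np.where(f >= 0.0, 1, -1)
    starts = _segment_bounds(sign)
    ends = np.concatenate([starts[1:], [len(f)]])
    maxima: List[ExtremumPoint] = []
    minima: List[ExtremumPoint] = []
    for j, (lo, hi) in enumerate(zip(starts, ends)):
        seg = f[lo:hi]
        idx = lo + int(np.argmax(np.abs(seg)))  # argmax returns earliest tie
        if sign[lo] > 0:
            maxima.append(ExtremumPoint(float(f[idx]), float(t[idx]), "max", j))
        else:
            minima.append(ExtremumPoint(float(f[idx]), float(t[idx]), "min", j))
    return maxima, minima


def extrema_summary(
    maxima: Sequence[ExtremumPoint], minima: Sequence[ExtremumPoint]
) -> ExtremaSummary:
    """Arithmetic means and global extrema of the two extrema sets."""
    if not maxima:
        raise MissingExtremaError("maxima set is empty")
    if not minima:
        raise MissingExtremaError("minima set is empty")
    max_vals = np.array([m.value for m in maxima])
    min_vals = np.array([m.value for m in minima])
    return ExtremaSummary(
        avg_local_max=float(max_vals.mean()),
        avg_local_min=float(min_vals.mean()),
        global_max=float(max_vals.max()),
        global_min=float(min_vals.min()),
    )


def outlier_quartile(values: Sequence[float], c: float = 1.5) -> np.ndarray:
    """Quartile-fence outlier mask: v outside [Q1 - c IQR, Q3 + c IQR].

    Quartiles are linear interpolations of the order statistics at
    position (n-1)p + 1 (one-based), i.e. the conventional linear
    quantile estimator.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 4:
        raise InsufficientDataError("quartile outlier test needs >= 4 values")
    q1, q3 = np.quantile(v, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    return (v > q3 + c * iqr) | (v < q1 - c * iqr)


def outlier_max_vs_mean(
    points: Sequence[Tuple[float, float]], c: float = 1.5
) -> Tuple[bool, Tuple[float, float]]:
    """Maximum-versus-mean outlier test on a sign-pure (value, time) set.

    The absolutely largest value y* is compared against the mean absolute
    value of the remaining set; y* is an outlier iff y* >= c * mean.
    Scale-invariant by construction: only the ratio matters.

    Returns ``(is_outlier, (y_star, t_star))`` with the signed value.
    """
    pts = list(points)
    if len(pts) < 2:
        raise InsufficientDataError("max-vs-mean outlier test needs >= 2 points")
    vals = np.array([p[0] for p in pts], dtype=float)
    if not (np.all(vals >= 0) or np.all(vals < 0)):
        raise InvalidInputError("values must be all non-negative or all negative")
    star = int(np.argmax(np.abs(vals)))
    y_star = float(vals[star])
    rest = np.abs(np.delete(vals, star))
    mean_rest = float(rest.mean())
    return bool(abs(y_star) >= c * mean_rest), (y_star, float(pts[star][1]))


def distribution_monitor(
    extrema: Sequence[ExtremumPoint],
    spec: HistogramSpec,
    kind: Literal["max", "min"],
    c: float = 1.5,
) -> Optional[float]:
    """Flag noise-dominated low-magnitude extrema bins as irrelevant.

    Extrema magnitudes are histogrammed into equidistant bins of width
    ``spec.bin_width`` anchored at magnitude 0.  The counts of the five
    lowest-magnitude bins are tested against each other with the
    quartile outlier identifier.  If at least one bin stands out, the
    irrelevance bound is the highest upper bin edge (maxima) or lowest
    lower edge (minima) among the outlier bins, then clamped so it never
    lies inside the +-clamp noise band.  Returns ``None`` when no bin
    has outlier character.
    """
    if not extrema:
        raise InvalidInputError("extrema set is empty")
    h = spec.bin_width
    n_bins = int(np.floor(spec.limit / h + 1e-9))
    if n_bins < 5:
        raise InsufficientBinsError(
            f"limit {spec.limit} accommodates only {n_bins} bins of width {h}; "
            "the monitor compares five"
        )
    mags = np.abs([e.value for e in extrema])
    # bin b (1-based) covers magnitudes [(b-1)h, bh)
    idx = np.floor(mags / h).astype(int)
    counts = np.array([(idx == b).sum() for b in range(5)], dtype=float)
    flagged = outlier_quartile(counts, c=c)
    if not flagged.any():
        return None
    bins = np.nonzero(flagged)[0] + 1  # 1-based
    if kind == "max":
        bound = float(bins.max() * h)
        return max(bound, spec.clamp)
    bound = float(-(bins.max() * h))
    return min(bound, -spec.clamp)
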
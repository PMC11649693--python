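"""Signal-analysis primitives: autocorrelation, extrema, outliers, monitor."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import nearfall as nf
from nearfall.errors import (
    DegenerateSignalError,
    InsufficientBinsError,
    InsufficientDataError,
    MissingExtremaError,
)
from nearfall.subroutines import ExtremumPoint, first_dominant_period


class TestAutocorrelation:
    def test_normalisation_r0(self, rng):
        ac = nf.autocorrelation(rng.normal(size=200), 0.01, 1.0)
        assert ac.r[0] == pytest.approx(1.0)

    def test_constant_signal_closed_form(self):
        # f = 3 over 10 samples: c_n = (10 - n) * 9, so r at lag index 5 is 0.5
        ac = nf.autocorrelation(np.full(10, 3.0), 1.0, 9.0)
        assert np.allclose(ac.r, (10 - np.arange(10)) / 10.0)
        assert ac.r[5] == pytest.approx(0.5)

    def test_sinusoid_peak_at_period(self):
        period, dt = 0.5, 0.005  # P/100
        t = np.arange(0, 10 * period, dt)
        ac = nf.autocorrelation(np.sin(2 * np.pi * t / period), dt, 3 * period)
        lag, _ = nf.dominant_periods(ac)[0]
        assert abs(lag - period) <= dt

    def test_zero_signal_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            nf.autocorrelation(np.zeros(100), 0.01, 0.5)

    def test_scale_invariance(self, rng):
        f = rng.normal(size=500)
        a1 = nf.autocorrelation(f, 0.01, 1.0)
        a2 = nf.autocorrelation(5.7 * f, 0.01, 1.0)
        assert np.allclose(a1.r, a2.r)


class TestDominantPeriods:
    def test_monotone_decay_empty(self):
        ac = nf.autocorrelation(np.full(50, 2.0), 1.0, 40.0)
        assert nf.dominant_periods(ac) == []

    def test_sinusoid_harmonic_peaks(self):
        period, dt = 0.4, 0.004
        t = np.arange(0, 12 * period, dt)
        peaks = nf.dominant_periods(
            nf.autocorrelation(np.sin(2 * np.pi * t / period), dt, 3.2 * period)
        )
        lags = sorted(lag for lag, _ in peaks)
        for k, lag in enumerate(lags, start=1):
            assert abs(lag - k * period) <= dt

    def test_white_noise_peaks_small(self, rng):
        ac = nf.autocorrelation(rng.normal(size=10_000), 0.01, 25.0)
        peaks = nf.dominant_periods(ac)
        assert max(r for _, r in peaks) < 0.3

    def test_first_dominant_prefers_fundamental(self):
        period, dt = 0.5, 0.01
        t = np.arange(0, 20 * period, dt)
        ac = nf.autocorrelation(np.sin(2 * np.pi * t / period), dt, 5 * period)
        assert first_dominant_period(ac) == pytest.approx(period, abs=dt)


class TestLocalExtrema:
    def test_tie_broken_by_earliest_time(self):
        maxima, minima = nf.local_extrema([2.0, 5.0, 5.0, 1.0])
        assert minima == []
        assert len(maxima) == 1
        assert maxima[0].value == 5.0 and maxima[0].time == 1.0

    def test_sine_two_periods(self):
        t = np.arange(0, 1.0, 0.001)
        maxima, minima = nf.local_extrema(np.sin(4 * np.pi * t), t)
        assert len(maxima) == 2 and len(minima) == 2
        assert all(m.value == pytest.approx(1.0, abs=1e-3) for m in maxima)
        assert all(m.value == pytest.approx(-1.0, abs=1e-3) for m in minima)

    def test_strictly_negative_single_segment(self):
        maxima, minima = nf.local_extrema([-3.0, -1.0, -4.0])
        assert maxima == []
        assert len(minima) == 1 and minima[0].value == -4.0

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=60))
    def test_segmentation_partition(self, values):
        """Each sample lies in exactly one sign-pure segment; segments and
        extrema counts agree."""
        maxima, minima = nf.local_extrema(values)
        f = np.asarray(values)
        sign = np.where(f >= 0, 1, -1)
        n_segments = 1 + int(np.sum(sign[1:] != sign[:-1]))
        assert len(maxima) + len(minima) == n_segments
        assert all(m.value >= 0 for m in maxima)
        assert all(m.value < 0 for m in minima)


class TestExtremaSummary:
    def test_arithmetic(self):
        mx = [ExtremumPoint(2.0, 0.0, "max", 0), ExtremumPoint(4.0, 1.0, "max", 2)]
        mn = [ExtremumPoint(-1.0, 0.5, "min", 1)]
        s = nf.extrema_summary(mx, mn)
        assert s.avg_local_max == 3.0 and s.global_max == 4.0
        assert s.avg_local_min == -1.0 and s.global_min == -1.0
        assert s.global_max >= s.avg_local_max

    def test_single_maximum_degenerate(self):
        mx = [ExtremumPoint(5.0, 0.0, "max", 0)]
        mn = [ExtremumPoint(-2.0, 1.0, "min", 1)]
        s = nf.extrema_summary(mx, mn)
        assert s.avg_local_max == s.global_max == 5.0

    def test_random_sets_match_brute_force(self, rng):
        mx = [ExtremumPoint(v, i, "max", i) for i, v in enumerate(rng.uniform(0, 9, 17))]
        mn = [ExtremumPoint(-v, i, "min", i) for i, v in enumerate(rng.uniform(0.1, 9, 11))]
        s = nf.extrema_summary(mx, mn)
        assert s.avg_local_max == pytest.approx(np.mean([m.value for m in mx]))
        assert s.global_min == min(m.value for m in mn)

    def test_empty_set_error(self):
        with pytest.raises(MissingExtremaError):
            nf.extrema_summary([], [ExtremumPoint(-1.0, 0.0, "min", 0)])


class TestOutlierQuartile:
    def test_all_equal_no_outliers(self):
        assert not nf.outlier_quartile([3.0, 3.0, 3.0, 3.0]).any()

    def test_worked_example(self):
        # {1,2,3,4,100}: Q1=2, Q3=4, fences [-1, 7] -> only 100 flagged
        mask = nf.outlier_quartile([1, 2, 3, 4, 100], c=1.5)
        assert mask.tolist() == [False, False, False, False, True]

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            nf.outlier_quartile([1.0, 2.0, 3.0])


class TestOutlierMaxVsMean:
    def test_worked_example(self):
        is_out, (y, x) = nf.outlier_max_vs_mean([(10, 0), (2, 1), (2, 2), (2, 3)])
        assert is_out and y == 10 and x == 0

    def test_equal_magnitudes_not_outlier(self):
        is_out, _ = nf.outlier_max_vs_mean([(4, 0), (4, 1), (4, 2)])
        assert not is_out

    @given(st.floats(0.1, 100), st.lists(st.floats(0.5, 5), min_size=3, max_size=12))
    def test_scale_invariance(self, scale, values):
        pts = [(v, float(i)) for i, v in enumerate(values)]
        scaled = [(v * scale, x) for v, x in pts]
        assert nf.outlier_max_vs_mean(pts)[0] == nf.outlier_max_vs_mean(scaled)[0]

    def test_negative_set(self):
        is_out, (y, _) = nf.outlier_max_vs_mean([(-9, 0), (-2, 1), (-2, 2)])
        assert is_out and y == -9


def _extrema(values, kind="max"):
    return [ExtremumPoint(v if kind == "max" else -v, float(i), kind, i)
            for i, v in enumerate(values)]


class TestDistributionMonitor:
    spec = nf.HistogramSpec(bin_width=1.0, limit=5.0, clamp=2.0)

    def test_noise_heavy_first_bin_flagged(self):
        # counts {500, 3, 2, 3, 2} in bins 1-5: bin 1 is a quartile outlier,
        # so the bound is bin 1's upper edge, raised to the clamp
        values = [0.5] * 500 + [1.5] * 3 + [2.5] * 2 + [3.5] * 3 + [4.5] * 2
        bound = nf.distribution_monitor(_extrema(values), self.spec, "max")
        assert bound == pytest.approx(2.0)  # max(1.0, clamp)

    def test_uniform_counts_none(self):
        values = [0.5, 1.5, 2.5, 3.5, 4.5] * 4
        assert nf.distribution_monitor(_extrema(values), self.spec, "max") is None

    def test_minima_bound_clamped_negative(self):
        values = [0.5] * 300 + [1.5, 2.5, 3.5, 4.5]
        bound = nf.distribution_monitor(_extrema(values, "min"), self.spec, "min")
        assert bound == pytest.approx(-2.0)

    def test_bound_never_inside_clamp(self, rng):
        for _ in range(20):
            values = rng.uniform(0, 5, size=rng.integers(10, 200))
            bound = nf.distribution_monitor(_extrema(values), self.spec, "max")
            if bound is not None:
                assert bound >= self.spec.clamp

    def test_insufficient_bins(self):
        with pytest.raises(InsufficientBinsError):
            nf.distribution_monitor(
                _extrema([1.0, 2.0]), nf.HistogramSpec(2.0, 5.0, 1.0), "max"
            )
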
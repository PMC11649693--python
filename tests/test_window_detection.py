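"""Observation-window detection: necessary-condition logic and refinement."""

import numpy as np
import pytest

import nearfall as nf
from nearfall.errors import ConfigurationError
from nearfall.synthetic import PerturbationSpec, TrialSpec


def _trip_trial(profile, onset=5.0, scale=1.5, seed=42, duration=10.0):
    spec = TrialSpec(
        task="walking",
        perturbation=PerturbationSpec(type="trip", onset=onset, magnitude_scale=scale),
        duration=duration,
    )
    return nf.generate_trial(spec, profile, seed=seed)


class TestDetectWindows:
    def test_baseline_has_no_windows(self, baselines, thresholds):
        for trial in baselines:
            assert nf.detect_windows(trial.kin, thresholds) == []

    def test_injected_transient_yields_one_window(self, profile, thresholds):
        kin, label = _trip_trial(profile, onset=5.0)
        windows = nf.detect_windows(kin, thresholds)
        assert len(windows) == 1
        w = windows[0]
        assert w.onset <= label.onset + 0.2
        assert w.offset >= label.onset

    def test_omega_only_anomaly_is_ignored(self, profile, thresholds):
        """A pick-and-drop style trunk bend exceeds the velocity band but
        not the acceleration band: the joint condition rejects it."""
        kin, _ = nf.generate_trial(
            TrialSpec(task="pick_and_drop", duration=10.0), profile, seed=7
        )
        assert nf.detect_windows(kin, thresholds) == []

    def test_missing_thresholds_rejected(self, profile):
        kin, _ = _trip_trial(profile)
        with pytest.raises(ConfigurationError):
            nf.detect_windows(kin, None)

    def test_ratio_monotonicity(self, profile, thresholds):
        kin, _ = _trip_trial(profile, scale=1.4)
        counts = [
            len(nf.detect_windows(kin, thresholds, ratio=r))
            for r in (1.05, 1.15, 1.3, 1.6, 2.5)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_windows_disjoint_and_sorted(self, profile, thresholds):
        spec = TrialSpec(
            task="walking",
            perturbation=PerturbationSpec(type="trip", onset=3.0),
            duration=12.0,
        )
        kin, _ = nf.generate_trial(spec, profile, seed=3)
        # add a second transient far away by injecting another trial's tail
        kin2, _ = nf.generate_trial(
            TrialSpec(
                task="walking",
                perturbation=PerturbationSpec(type="slip", onset=9.0),
                duration=12.0,
            ),
            profile,
            seed=3,
        )
        merged = nf.KinematicsSeries(
            t=kin.t,
            omega_y=np.where(kin.t < 6.0, kin.omega_y, kin2.omega_y),
            alpha_y=np.where(kin.t < 6.0, kin.alpha_y, kin2.alpha_y),
        )
        windows = nf.detect_windows(merged, kin_thresholds := nf.calibrate(
            [nf.generate_baseline(profile, seed=profile.seed + 101 + j) for j in range(3)]
        ))
        onsets = [w.onset for w in windows]
        assert onsets == sorted(onsets)
        for a, b in zip(windows, windows[1:]):
            assert a.offset < b.onset

    def test_shift_equivariance(self, profile, thresholds):
        kin, _ = _trip_trial(profile, onset=4.0)
        delta = 20.0
        shifted = nf.KinematicsSeries(
            t=kin.t + delta, omega_y=kin.omega_y, alpha_y=kin.alpha_y
        )
        w0 = nf.detect_windows(kin, thresholds)
        w1 = nf.detect_windows(shifted, thresholds)
        assert len(w0) == len(w1) == 1
        assert w1[0].onset == pytest.approx(w0[0].onset + delta, abs=1e-6)
        assert w1[0].offset == pytest.approx(w0[0].offset + delta, abs=1e-6)

    def test_invariant_to_appended_quiet_baseline(self, profile, thresholds):
        kin, _ = _trip_trial(profile, onset=5.0)
        dt = kin.dt
        pad = np.zeros(200)
        t_ext = np.arange(len(kin.t) + 400) * dt
        padded = nf.KinematicsSeries(
            t=t_ext,
            omega_y=np.concatenate([pad, kin.omega_y, pad]),
            alpha_y=np.concatenate([pad, kin.alpha_y, pad]),
        )
        w0 = nf.detect_windows(kin, thresholds)
        w1 = nf.detect_windows(padded, thresholds)
        assert len(w0) == len(w1) == 1
        assert w1[0].onset == pytest.approx(w0[0].onset + 200 * dt, abs=2 * dt)


class TestOnsetRefinement:
    def test_onset_immediately_after_zero_crossing(self, profile, thresholds):
        kin, _ = _trip_trial(profile)
        w = nf.detect_windows(kin, thresholds)[0]
        i = int(np.searchsorted(kin.t, w.onset))
        assert kin.t[i] == pytest.approx(w.onset)
        # sign map changes between the previous sample and the onset sample
        s_prev = 1 if kin.alpha_y[i - 1] >= 0 else -1
        s_here = 1 if kin.alpha_y[i] >= 0 else -1
        assert s_prev != s_here

    def test_constructed_pulse_onset(self):
        dt = 0.01
        t = np.arange(0, 4, dt)
        alpha = np.where((t >= 2.0) & (t < 2.2), 50.0 * np.sin(np.pi * (t - 2.0) / 0.2), -0.5)
        onset, truncated = nf.refine_onset(2.1, nf.KinematicsSeries(t=t, omega_y=alpha * 0, alpha_y=alpha))
        assert not truncated
        assert onset == pytest.approx(2.0, abs=dt)

    def test_extreme_at_first_sample_truncates(self):
        t = np.arange(0, 2, 0.01)
        alpha = np.full_like(t, 5.0)
        onset, truncated = nf.refine_onset(0.0, nf.KinematicsSeries(t=t, omega_y=alpha, alpha_y=alpha))
        assert truncated and onset == t[0]


class TestOffsetRefinement:
    def test_isolated_pulse_offset_at_trailing_crossing(self, profile, thresholds):
        kin, label = _trip_trial(profile, onset=5.0)
        w = nf.detect_windows(kin, thresholds)[0]
        # transient decays within ~1 s; offset lies shortly after the event
        assert label.onset < w.offset < label.onset + 2.5

    def test_two_close_pulses_merge(self, profile, thresholds):
        period = thresholds.step_period
        spec = TrialSpec(
            task="standing",
            perturbation=PerturbationSpec(type="anterior_loss", onset=4.0),
            duration=10.0,
        )
        kin, _ = nf.generate_trial(spec, profile, seed=11)
        # clone the transient half a step period later: same cluster
        kin2, _ = nf.generate_trial(
            TrialSpec(
                task="standing",
                perturbation=PerturbationSpec(
                    type="anterior_loss", onset=4.0 + 0.5 * period
                ),
                duration=10.0,
            ),
            profile,
            seed=11,
        )
        combo = nf.KinematicsSeries(
            t=kin.t,
            omega_y=kin.omega_y + kin2.omega_y,
            alpha_y=kin.alpha_y + kin2.alpha_y,
        )
        assert len(nf.detect_windows(combo, thresholds)) == 1

    def test_two_far_pulses_stay_separate(self, profile, thresholds):
        period = thresholds.step_period
        t0 = 3.0
        t1 = t0 + 3.0 * period + 1.5  # beyond one step period after decay
        spec = TrialSpec(
            task="standing",
            perturbation=PerturbationSpec(type="anterior_loss", onset=t0),
            duration=12.0,
        )
        kin, _ = nf.generate_trial(spec, profile, seed=13)
        kin2, _ = nf.generate_trial(
            TrialSpec(
                task="standing",
                perturbation=PerturbationSpec(type="anterior_loss", onset=t1),
                duration=12.0,
            ),
            profile,
            seed=13,
        )
        combo = nf.KinematicsSeries(
            t=kin.t,
            omega_y=kin.omega_y + kin2.omega_y,
            alpha_y=kin.alpha_y + kin2.alpha_y,
        )
        assert len(nf.detect_windows(combo, thresholds)) == 2
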
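"""Three-step recovery-vs-ADL analysis, preceding task and perturbation type."""

import numpy as np
import pytest

import nearfall as nf
from nearfall.synthetic import PerturbationSpec, TrialSpec


def _trial(profile, task, ptype=None, onset=5.0, seed=42, duration=10.0, scale=1.5):
    pert = (
        PerturbationSpec(type=ptype, onset=onset, magnitude_scale=scale)
        if ptype
        else None
    )
    if task in ("standing", "sit_to_stand"):
        duration = 8.0
    return nf.generate_trial(
        TrialSpec(task=task, perturbation=pert, duration=duration), profile, seed=seed
    )


class TestStepOne:
    def test_running_window_is_periodic_adl(self, profile, thresholds):
        kin, _ = _trial(profile, "running")
        windows = nf.detect_windows(kin, thresholds)
        assert windows  # elevated amplitudes satisfy the necessary condition
        verdict, trace = nf.step1_periodicity_vs_outliers(windows[0], kin, thresholds)
        assert verdict == "ADL"
        assert trace.condition == "periodic_ADL"
        assert trace.evidence["n_repetitions"] >= 3

    def test_trip_window_is_recovery(self, profile, thresholds):
        """A window holding the transient plus local gait context fires
        the correlated-outlier condition; the refined window itself can
        be too tight to carry context, in which case the trial is still
        caught by step 3 (checked in TestClassifyTrial)."""
        from nearfall.window_detection import ObservationWindow

        kin, _ = _trial(profile, "walking", "trip")
        w0 = nf.detect_windows(kin, thresholds)[0]
        w = ObservationWindow(
            onset=w0.onset - 0.8,
            offset=w0.offset + 0.8,
            temporary_bounds=w0.temporary_bounds,
            extended_bounds=w0.extended_bounds,
        )
        verdict, trace = nf.step1_periodicity_vs_outliers(w, kin, thresholds)
        assert verdict == "recovery"
        assert trace.condition == "correlated_outliers"
        dt = abs(
            trace.evidence["alpha_outlier"]["time"]
            - trace.evidence["omega_outlier"]["time"]
        )
        assert dt <= 0.15

    def test_two_repetitions_undecided(self, thresholds):
        """A short quiet window with two moderate maxima satisfies neither
        condition."""
        dt = 0.01
        t = np.arange(0, 3, dt)
        alpha = np.zeros_like(t)
        for centre in (1.0, 1.5):
            alpha += 10.0 * np.exp(-0.5 * ((t - centre) / 0.03) ** 2)
        alpha -= 2.0
        kin = nf.KinematicsSeries(t=t, omega_y=np.zeros_like(t) + 0.01, alpha_y=alpha)
        from nearfall.window_detection import ObservationWindow

        w = ObservationWindow(
            onset=0.5, offset=2.5, temporary_bounds=(1.0, 1.5), extended_bounds=(0.5, 2.5)
        )
        verdict, _ = nf.step1_periodicity_vs_outliers(w, kin, thresholds)
        assert verdict == "undecided"


class TestStepThree:
    def test_lean_release_recovery(self, profile, thresholds):
        kin, _ = _trial(profile, "standing", "anterior_loss", onset=4.0)
        w = nf.detect_windows(kin, thresholds)[0]
        verdict, trace = nf.step3_boundary_outliers(w, kin, thresholds)
        assert verdict == "recovery"
        assert trace.condition == "boundary_outliers"

    def test_separated_outliers_are_adl(self, thresholds):
        """Outlier-sized spikes 0.4 s apart in the two signals miss the
        correlation interval."""
        dt = 0.01
        t = np.arange(0, 8, dt)
        alpha = 0.5 * np.sin(2 * np.pi * 1.5 * t)
        omega = 0.02 * np.sin(2 * np.pi * 1.5 * t)
        alpha = alpha + 60.0 * np.exp(-0.5 * ((t - 4.0) / 0.03) ** 2)
        omega = omega + 1.2 * np.exp(-0.5 * ((t - 4.4) / 0.05) ** 2)
        kin = nf.KinematicsSeries(t=t, omega_y=omega, alpha_y=alpha)
        from nearfall.window_detection import ObservationWindow

        w = ObservationWindow(
            onset=3.8, offset=4.6, temporary_bounds=(4.0, 4.4), extended_bounds=(3.8, 4.6)
        )
        verdict, _ = nf.step3_boundary_outliers(w, kin, thresholds)
        assert verdict == "ADL"


class TestPrecedingTask:
    def test_quiet_interval_is_standing(self, profile, thresholds, references):
        kin, label = _trial(profile, "standing", "anterior_loss", onset=4.0)
        w = nf.detect_windows(kin, thresholds)[0]
        assert nf.classify_preceding_task(kin, w.onset, thresholds, references) == "standing"

    def test_walking_interval(self, profile, thresholds, references):
        kin, _ = _trial(profile, "walking", "trip", onset=6.0)
        w = nf.detect_windows(kin, thresholds)[0]
        assert nf.classify_preceding_task(kin, w.onset, thresholds, references) == "walking"

    def test_running_interval(self, profile, thresholds, references):
        kin, _ = _trial(profile, "running")
        # probe an interior time point: four periods of running precede it
        assert (
            nf.classify_preceding_task(kin, 6.0, thresholds, references) == "running"
        )


class TestPerturbationType:
    @pytest.mark.parametrize(
        "task,ptype",
        [
            ("walking", "trip"),
            ("walking", "slip"),
            ("standing", "anterior_loss"),
            ("standing", "posterior_loss"),
        ],
    )
    def test_types_recovered(self, profile, thresholds, references, task, ptype):
        kin, label = _trial(profile, task, ptype, onset=4.5, seed=21)
        calls = nf.classify_trial(kin, thresholds, references)
        recoveries = [c for c in calls if c.is_recovery]
        assert len(recoveries) == 1
        assert recoveries[0].type == ptype
        assert recoveries[0].preceding == label.preceding

    def test_sign_convention_flip_swaps_labels(self, profile, thresholds, references):
        kin, _ = _trial(profile, "walking", "trip", onset=4.5, seed=21)
        cfg = nf.FrameworkConfig(forward_pitch_positive=False)
        calls = nf.classify_trial(kin, thresholds, references, cfg)
        rec = [c for c in calls if c.is_recovery]
        assert rec and rec[0].type == "slip"

    def test_axis_flip_antisymmetry(self, profile, thresholds):
        """Negating both signals, with mirrored thresholds, swaps
        trip<->slip while preserving the recovery verdict.  (Thresholds
        are mirrored rather than recalibrated: the calibration routine
        itself is sign-specific because touchdown maxima are positive
        by physiology.)"""

        def mirror(sig):
            return nf.SignalThresholds(
                global_max=-sig.global_min,
                global_min=-sig.global_max,
                avg_local_max=-sig.avg_local_min,
                avg_local_min=-sig.avg_local_max,
                irrelevance_max=None if sig.irrelevance_min is None else -sig.irrelevance_min,
                irrelevance_min=None if sig.irrelevance_max is None else -sig.irrelevance_max,
            )

        th = thresholds
        th_neg = nf.PersonalisedThresholds(
            step_frequency=th.step_frequency,
            omega_y=mirror(th.omega_y),
            alpha_y=mirror(th.alpha_y),
        )
        kin, _ = _trial(profile, "walking", "trip", onset=4.5, seed=21)
        neg = nf.KinematicsSeries(t=kin.t, omega_y=-kin.omega_y, alpha_y=-kin.alpha_y)
        calls = nf.classify_trial(kin, th)
        calls_neg = nf.classify_trial(neg, th_neg)
        rec = [c for c in calls if c.is_recovery]
        rec_neg = [c for c in calls_neg if c.is_recovery]
        assert len(rec) == len(rec_neg) == 1
        assert rec[0].type == "trip" and rec_neg[0].type == "slip"


class TestClassifyTrial:
    def test_unperturbed_walking_empty(self, profile, thresholds, references):
        kin, _ = _trial(profile, "walking", seed=2)
        assert nf.classify_trial(kin, thresholds, references) == []

    def test_every_window_gets_exactly_one_verdict(self, profile, thresholds, references):
        kin, _ = _trial(profile, "running", seed=5)
        calls = nf.classify_trial(kin, thresholds, references)
        for c in calls:
            assert c.is_recovery == (c.type != "none") or c.type == "none"
            assert c.trace.step in (1, 2, 3)
            assert (c.type != "none") == (c.is_recovery and c.preceding != "running")

    def test_two_separated_perturbations_two_calls(self, profile, thresholds, references):
        k1, _ = _trial(profile, "walking", "trip", onset=3.0, seed=31, duration=14.0)
        k2, _ = _trial(profile, "walking", "slip", onset=10.0, seed=31, duration=14.0)
        combo = nf.KinematicsSeries(
            t=k1.t,
            omega_y=np.where(k1.t < 7.0, k1.omega_y, k2.omega_y),
            alpha_y=np.where(k1.t < 7.0, k1.alpha_y, k2.alpha_y),
        )
        calls = nf.classify_trial(combo, thresholds, references)
        rec = [c for c in calls if c.is_recovery]
        assert len(rec) == 2
        assert rec[0].window.onset < rec[1].window.onset
        assert [c.type for c in rec] == ["trip", "slip"]

    def test_monotone_in_magnitude(self, profile, thresholds, references):
        """Detection does not get worse as perturbations grow (noise fixed)."""
        hits = []
        for scale in (1.3, 1.8, 2.5):
            ok = 0
            for seed in range(6):
                kin, _ = _trial(profile, "walking", "trip", onset=4.0, seed=60 + seed, scale=scale)
                calls = nf.classify_trial(kin, thresholds, references)
                ok += any(c.is_recovery and c.type == "trip" for c in calls)
            hits.append(ok)
        assert hits[0] <= hits[1] + 1 and hits[1] <= hits[2] + 1  # allow one-off noise
        assert hits[-1] >= 5
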
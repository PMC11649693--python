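"""Labelled synthetic trunk-kinematics trials with machine-readable ground truth.

The generator emulates the statistical structure the detection framework
assumes, so that every stage is testable without recorded data.  All
deterministic signal content is constructed as analytic (angular
velocity, angular acceleration) derivative pairs, so a single-sensor
route that differences the velocity channel sees the same events
through its own filter; only sensor noise is drawn per channel.

* **Baseline walking** — band-limited harmonics of the angular velocity
  at the step frequency plus, at every touchdown, a Gaussian-windowed
  velocity wavelet whose analytic derivative forms the sharp
  angular-acceleration pulse (the harmonic acceleration terms vanish at
  the touchdown instants, so the realised touchdown maxima estimate the
  pulse amplitudes directly).
* **Sensor noise** — white gyroscope noise, white cluster-solution
  acceleration noise, and impact-locked gyroscope *vibration* noise
  that scales with each impact's magnitude.  The vibration term is what
  separates the sensing routes: the cluster's algebraic acceleration
  does not inherit it, whereas numerical differencing amplifies it into
  artefact extrema of near-touchdown magnitude.
* **ADL templates** — running (elevated cadence and amplitudes, sharper
  impacts), standing (low-magnitude sway), sit-to-stand and stairs
  (sub-threshold variants), pick-and-drop (walking paused into stance,
  a large bend-velocity anomaly, and a load-release jolt whose
  acceleration peak stays below the detection band on clean signals) —
  all with per-trial intensity variation.
* **Perturbation transients** — a sustained damped velocity oscillation
  plus an impact-like wavelet, both direction-signed and scaled
  relative to the profile's global references, masked to start at the
  onset; the first lobes form a time-correlated outlier pair within
  the correlation interval by construction, and the ongoing gait
  pattern is transiently suppressed as a real recovery does.

Every trial carries a :class:`TrialLabel` with the event ground truth
(type, onset, preceding task) sufficient to score any stage in
isolation.  All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidInputError
from .kinematics import (
    ClusterGeometry,
    ClusterSeries,
    KinematicsSeries,
    default_geometry,
    rigid_body_forward_model,
)
from .thresholds import BaselineTrial

TaskName = Literal[
    "walking", "running", "standing", "sit_to_stand", "stairs", "pick_and_drop"
]
PerturbationName = Literal["trip", "slip", "anterior_loss", "posterior_loss"]

#: Impact magnitude (rad/s^2) at which ``vibration_omega`` applies; the
#: vibration level scales linearly with each impact's amplitude.
_VIB_REF_ALPHA = 32.0

#: Reference trial composition used as the default benchmark mix
#: (counts over 627 trials: 179 perturbed, 448 ADL).
DEFAULT_MIX: Dict[str, int] = {
    "trip": 74,
    "slip": 16,
    "anterior_loss": 62,
    "posterior_loss": 27,
    "walking": 168,
    "running": 72,
    "stairs": 82,
    "sit_to_stand": 84,
    "pick_and_drop": 42,
}

#: Perturbation-to-context mapping: which task hosts each perturbation
#: and which locomotor state precedes the onset.
PERTURBATION_CONTEXT: Dict[str, str] = {
    "trip": "walking",
    "slip": "walking",
    "anterior_loss": "standing",
    "posterior_loss": "standing",
}

#: Initial trunk-pitch direction per perturbation type under the
#: forward-pitch-positive sign convention.
PERTURBATION_SIGN: Dict[str, int] = {
    "trip": +1,
    "slip": -1,
    "anterior_loss": +1,
    "posterior_loss": -1,
}


@dataclass
class GaitProfile:
    """Subject-level generative parameters for baseline walking.

    Defaults emulate a healthy adult walking at about 1.4 m/s: a step
    (touchdown) frequency of 1.95 Hz (117 steps/min cadence) and a
    touchdown-pulse amplitude of 32 rad/s^2, the centre of the cohort
    range for averaged-local trunk angular-acceleration maxima.
    """

    step_frequency: float = 1.95          # Hz, touchdown events per second
    omega_amp_1: float = 0.45             # rad/s, fundamental pitch harmonic
    omega_amp_2: float = 0.05             # rad/s, second harmonic
    omega_amp_3: float = 0.10             # rad/s, third harmonic
    pulse_amplitude: float = 32.0         # rad/s^2, touchdown pulse peak
    pulse_sigma: float = 0.05             # s, touchdown-wavelet envelope width
    pulse_carrier_hz: float = 5.0         # Hz, touchdown-wavelet carrier
    pulse_jitter: float = 0.05            # relative sd of per-step amplitude
    noise_omega: float = 0.02             # rad/s, white gyro noise
    noise_alpha: float = 0.5              # rad/s^2, cluster-solution noise
    vibration_omega: float = 0.04         # rad/s, gyro vibration noise at a
                                          # walking-scale impact (scales with
                                          # impact magnitude)
    sample_rate: float = 100.0            # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "step_frequency",
            "omega_amp_1",
            "pulse_amplitude",
            "pulse_sigma",
            "sample_rate",
        ):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"GaitProfile.{name} must be positive")

    @property
    def step_period(self) -> float:
        return 1.0 / self.step_frequency

    @property
    def omega_global_ref(self) -> float:
        """Approximate global angular-velocity magnitude of the profile,
        harmonics plus the touchdown-wavelet velocity lobe."""
        lobe = 0.6 * self.pulse_amplitude / (2 * np.pi * self.pulse_carrier_hz)
        return self.omega_amp_1 + self.omega_amp_2 + self.omega_amp_3 + lobe

    @property
    def alpha_global_ref(self) -> float:
        """Approximate global angular-acceleration magnitude (jittered pulse peak)."""
        return self.pulse_amplitude * (1.0 + 2.0 * self.pulse_jitter)


@dataclass
class PerturbationSpec:
    """An injected balance perturbation."""

    type: PerturbationName
    onset: float                 # s, into the trial
    magnitude_scale: float = 1.5  # x the profile's global reference
    direction: Optional[int] = None  # +1 anterior, -1 posterior; default per type

    def __post_init__(self) -> None:
        if self.type not in PERTURBATION_CONTEXT:
            raise InvalidInputError(f"unknown perturbation type {self.type!r}")
        if self.magnitude_scale <= 1.0:
            raise InvalidInputError(
                "magnitude_scale must exceed 1 for a detectable event"
            )
        if self.direction is None:
            self.direction = PERTURBATION_SIGN[self.type]


@dataclass
class TrialSpec:
    """What to generate: a task, an optional perturbation, a duration."""

    task: TaskName
    perturbation: Optional[PerturbationSpec] = None
    duration: float = 12.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidInputError("duration must be positive")
        if self.perturbation is not None:
            host = PERTURBATION_CONTEXT[self.perturbation.type]
            if self.task != host:
                raise InvalidInputError(
                    f"perturbation {self.perturbation.type!r} occurs during "
                    f"{host!r}, not {self.task!r}"
                )
            if not 1.0 <= self.perturbation.onset <= self.duration - 2.0:
                raise InvalidInputError(
                    "perturbation onset must lie inside the trial "
                    "(>= 1 s from either end)"
                )


@dataclass
class TrialLabel:
    """Ground truth attached to a generated trial."""

    task: TaskName
    perturbed: bool
    type: Optional[PerturbationName] = None
    onset: Optional[float] = None
    preceding: Optional[str] = None
    magnitude_scale: Optional[float] = None


def _walking_signals(
    t: np.ndarray,
    rng: np.random.Generator,
    profile: GaitProfile,
    freq: float,
    pulse_amp: float,
    omega_scale: float = 1.0,
    carrier_scale: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray, dict]:
    """Noise-free walking-type signals plus per-step ground truth.

    ``carrier_scale`` raises the touchdown-wavelet carrier frequency for
    tasks with more forceful heel strikes (running): the impact content
    sharpens with magnitude, which keeps the wavelet's angular-velocity
    lobe commensurate with the harmonic velocity amplitudes.
    """
    w1 = profile.omega_amp_1 * omega_scale
    w2 = profile.omega_amp_2 * omega_scale
    w3 = profile.omega_amp_3 * omega_scale
    phi2 = np.pi / 2.0
    x = 2 * np.pi * freq * t
    # Harmonic phases are chosen so all harmonic acceleration terms
    # vanish at the touchdown times t_k = (k + 1/4)/f: the realised
    # touchdown maxima then estimate the pulse amplitudes directly.
    # The third harmonic gives the acceleration the multi-modal,
    # frequently zero-crossing shape of real trunk signals.
    omega = w1 * np.sin(x) + w2 * np.sin(2 * x + phi2) + w3 * np.sin(3 * x)
    alpha = 2 * np.pi * freq * (
        w1 * np.cos(x) + 2 * w2 * np.cos(2 * x + phi2) + 3 * w3 * np.cos(3 * x)
    )
    # Touchdown transients at t_k = (k + 1/4)/f, where all harmonic
    # acceleration terms vanish.  Each touchdown is a Gaussian-windowed
    # wavelet defined in the angular velocity (a brief oscillation of
    # the trunk at heel strike) whose analytic derivative supplies the
    # sharp angular-acceleration pulse; both channels therefore carry
    # consistent touchdown content, as a differencing sensor route
    # requires.  The wavelet integrates to zero: no net velocity change
    # per step.
    period = 1.0 / freq
    step_times = []
    peak_values = []
    vib_env = np.zeros_like(t)
    k = 1  # skip the partial step at the record start
    while (k + 0.25) * period < t[-1] - 0.5 * period:
        t_k = (k + 0.25) * period
        a_k = pulse_amp * (1.0 + profile.pulse_jitter * rng.standard_normal())
        o, a = _wavelet(
            t, t_k, a_k, profile.pulse_carrier_hz * carrier_scale, profile.pulse_sigma
        )
        omega = omega + o
        alpha = alpha + a
        # soft-tissue/impact vibration picked up by the gyroscope,
        # proportional to the impact magnitude
        vib_env = vib_env + (a_k / _VIB_REF_ALPHA) * np.exp(
            -0.5 * ((t - t_k) / profile.pulse_sigma) ** 2
        )
        step_times.append(t_k)
        peak_values.append(a_k)
        k += 1
    # Realised touchdown maxima of the clean composite signal: the
    # drawn pulse amplitudes minus the small overlap of neighbouring
    # lobes.  This, not the nominal draw, is the generator's ground
    # truth for what a calibrated averaged-local maximum should recover.
    realised = []
    for t_k in step_times:
        near = (t >= t_k - 0.06) & (t <= t_k + 0.06)
        if near.any():
            realised.append(float(alpha[near].max()))
    truth = {
        "step_frequency": freq,
        "step_times": np.array(step_times),
        "pulse_draws": np.array(peak_values),
        "pulse_peaks": np.array(realised),
        "pulse_amplitude": pulse_amp,
        "avg_touchdown_max": float(np.mean(realised)) if realised else np.nan,
        "vib_env": vib_env,
    }
    return omega, alpha, truth


def _standing_signals(
    t: np.ndarray, rng: np.random.Generator, profile: GaitProfile
) -> Tuple[np.ndarray, np.ndarray]:
    """Quiet bipedal stance: slow low-magnitude postural sway."""
    sway_f = 0.3
    omega = 0.03 * np.sin(2 * np.pi * sway_f * t + rng.uniform(0, 2 * np.pi))
    alpha = 2 * np.pi * sway_f * 0.03 * np.cos(2 * np.pi * sway_f * t)
    return omega, alpha


def _smooth_lobe(t: np.ndarray, centre: float, width: float, amp: float) -> Tuple[np.ndarray, np.ndarray]:
    """A Gaussian angular-velocity lobe and its analytic derivative."""
    g = np.exp(-0.5 * ((t - centre) / width) ** 2)
    omega = amp * g
    alpha = amp * g * (-(t - centre) / width**2)
    return omega, alpha


def _damped_sinusoid(
    t: np.ndarray, t0: float, amp: float, carrier_hz: float, tau: float
) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided damped angular-velocity sinusoid and its derivative.

    The velocity lobe starts at t0 with first-lobe sign = sign(amp) and
    is normalised so the first-lobe peak reaches ``amp`` exactly despite
    the decay envelope.  Returns ``(omega_component, alpha_component)``
    with the acceleration as the analytic time derivative, so both
    kinematic channels stay mutually consistent.
    """
    rel = t - t0
    omega = np.zeros_like(t)
    alpha = np.zeros_like(t)
    mask = rel >= 0
    u = rel[mask]
    c = 2 * np.pi * carrier_hz
    envelope_at_peak = np.exp(-1.0 / (4.0 * carrier_hz * tau))
    scale = amp / envelope_at_peak
    env = np.exp(-u / tau)
    omega[mask] = scale * env * np.sin(c * u)
    alpha[mask] = scale * env * (c * np.cos(c * u) - np.sin(c * u) / tau)
    return omega, alpha


def _wavelet(
    t: np.ndarray, t_k: float, alpha_peak: float, carrier_hz: float, sigma: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Gaussian-windowed velocity wavelet whose derivative peaks at
    ``alpha_peak`` at the wavelet centre; returns (omega, alpha)."""
    c = 2 * np.pi * carrier_hz
    b = alpha_peak / c
    u = t - t_k
    g = np.exp(-0.5 * (u / sigma) ** 2)
    omega = b * g * np.sin(c * u)
    alpha = b * g * (c * np.cos(c * u) - (u / sigma**2) * np.sin(c * u))
    return omega, alpha


def _gait_suppression(t: np.ndarray, t0: float, depth: float = 0.8, tau: float = 0.5) -> np.ndarray:
    """Multiplicative envelope modelling the disruption of the periodic
    gait pattern by a balance recovery response (recovers over ~tau)."""
    rel = t - t0
    env = np.ones_like(t)
    mask = rel >= 0
    env[mask] = 1.0 - depth * np.exp(-rel[mask] / tau)
    return env


def generate_baseline(
    profile: GaitProfile, duration: float = 12.0, seed: Optional[int] = None
) -> BaselineTrial:
    """Generate one unperturbed baseline walking trial for calibration."""
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    dt = 1.0 / profile.sample_rate
    t = np.arange(0.0, duration, dt)
    omega, alpha, truth = _walking_signals(
        t, rng, profile, profile.step_frequency, profile.pulse_amplitude
    )
    omega = omega + profile.noise_omega * rng.standard_normal(len(t))
    omega = omega + profile.vibration_omega * truth["vib_env"] * rng.standard_normal(len(t))
    alpha = alpha + profile.noise_alpha * rng.standard_normal(len(t))
    kin = KinematicsSeries(t=t, omega_y=omega, alpha_y=alpha)
    return BaselineTrial(
        kin=kin,
        subject_id=f"synthetic-{profile.seed}",
        ground_truth=truth,
    )


def generate_trial(
    spec: TrialSpec,
    profile: GaitProfile,
    seed: Optional[int] = None,
) -> Tuple[KinematicsSeries, TrialLabel]:
    """Generate one labelled trial according to its spec.

    Perturbations are injected as direction-signed damped-sinusoid
    transients in both signals, scaled relative to the profile's global
    references, with first-lobe peaks time-correlated by construction.
    """
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    dt = 1.0 / profile.sample_rate
    t = np.arange(0.0, spec.duration, dt)
    task = spec.task

    # Per-trial intensity: ADLs were performed over a range of speeds
    # and vigour in the emulated protocol (three walking speeds,
    # varying staircase effort), so amplitudes vary trial to trial.
    intensity = 1.0
    if task in ("walking", "pick_and_drop", "stairs", "running"):
        intensity = float(rng.uniform(0.85, 1.15))

    vib_env = np.zeros_like(t)
    if task in ("walking", "pick_and_drop"):
        omega, alpha, wtruth = _walking_signals(
            t,
            rng,
            profile,
            profile.step_frequency,
            profile.pulse_amplitude * intensity,
            omega_scale=intensity,
        )
        vib_env = wtruth["vib_env"]
    elif task == "running":
        omega, alpha, wtruth = _walking_signals(
            t,
            rng,
            profile,
            profile.step_frequency * 1.35,
            profile.pulse_amplitude * 4.1 * intensity,
            omega_scale=2.0 * intensity,
            carrier_scale=3.0,
        )
        vib_env = wtruth["vib_env"]
    elif task == "stairs":
        omega, alpha, wtruth = _walking_signals(
            t,
            rng,
            profile,
            profile.step_frequency * 0.9,
            profile.pulse_amplitude * 0.9 * intensity,
            omega_scale=0.9 * intensity,
        )
        vib_env = wtruth["vib_env"]
    elif task == "standing":
        omega, alpha = _standing_signals(t, rng, profile)
    elif task == "sit_to_stand":
        omega, alpha = _standing_signals(t, rng, profile)
        for centre, sign in ((spec.duration * 0.25, +1), (spec.duration * 0.75, -1)):
            o, a = _smooth_lobe(t, centre, 0.5, sign * 0.8 * profile.omega_global_ref)
            omega, alpha = omega + o, alpha + a
    else:
        raise InvalidInputError(f"unknown task {task!r}")

    if task == "pick_and_drop":
        # Bend-and-return excursions from momentary quiet stance: the
        # walking pattern pauses around each event (the object is
        # grabbed and released standing still), the trunk bend gives a
        # large omega anomaly, and grabbing/releasing the load adds an
        # impact-like jolt co-located with the return lobe whose
        # acceleration peak stays below the anomaly threshold — so the
        # task never satisfies the necessary condition on clean cluster
        # kinematics.
        drop_jolt = float(rng.uniform(0.65, 1.0))
        for centre, jolt in (
            (spec.duration * 0.3, 0.6 * drop_jolt),
            (spec.duration * 0.7, drop_jolt),
        ):
            stance = 1.0 - 0.9 * np.exp(-0.5 * ((t - centre) / 0.8) ** 2)
            omega = omega * stance
            alpha = alpha * stance
            for off, sign in ((-0.35, -1), (+0.35, +1)):
                o, a = _smooth_lobe(
                    t, centre + off, 0.35, sign * 1.4 * profile.omega_global_ref
                )
                omega, alpha = omega + o, alpha + a
            o, a = _wavelet(
                t,
                centre + 0.35,
                jolt * profile.alpha_global_ref,
                profile.pulse_carrier_hz,
                profile.pulse_sigma,
            )
            omega, alpha = omega + o, alpha + a
            vib_env = vib_env + (
                jolt * profile.alpha_global_ref / _VIB_REF_ALPHA
            ) * np.exp(-0.5 * ((t - (centre + 0.35)) / profile.pulse_sigma) ** 2)

    label = TrialLabel(task=task, perturbed=False)
    if spec.perturbation is not None:
        p = spec.perturbation
        sgn = p.direction
        # The recovery response disrupts the periodic gait pattern and
        # superposes (1) a sustained trunk swing — a slow damped
        # velocity oscillation — and (2) an impact-like wavelet carrying
        # the sharp angular-acceleration transient.  Both components are
        # analytic (omega, d omega/dt) pairs, so a differencing sensor
        # route sees the same event through its own filter.
        supp = _gait_suppression(t, p.onset)
        omega = omega * supp
        alpha = alpha * supp
        o_slow, a_slow = _damped_sinusoid(
            t, p.onset, sgn * p.magnitude_scale * profile.omega_global_ref, 2.5, 0.25
        )
        # The sharp component is centred half a carrier period after the
        # onset and masked to t >= onset: nothing of the response leaks
        # before the perturbation, and the velocity lobe is continuous
        # at the mask edge (sin(-pi) = 0).
        half_carrier = 0.5 / profile.pulse_carrier_hz
        o_sharp, a_sharp = _wavelet(
            t,
            p.onset + half_carrier,
            sgn * p.magnitude_scale * profile.alpha_global_ref,
            profile.pulse_carrier_hz,
            profile.pulse_sigma,
        )
        causal = t >= p.onset
        omega = omega + o_slow + o_sharp * causal
        alpha = alpha + a_slow + a_sharp * causal
        vib_env = vib_env * supp + causal * (
            p.magnitude_scale * profile.alpha_global_ref / _VIB_REF_ALPHA
        ) * np.exp(
            -0.5 * ((t - (p.onset + half_carrier)) / profile.pulse_sigma) ** 2
        )
        label = TrialLabel(
            task=task,
            perturbed=True,
            type=p.type,
            onset=p.onset,
            preceding=PERTURBATION_CONTEXT[p.type],
            magnitude_scale=p.magnitude_scale,
        )

    omega = omega + profile.noise_omega * rng.standard_normal(len(t))
    omega = omega + profile.vibration_omega * vib_env * rng.standard_normal(len(t))
    alpha = alpha + profile.noise_alpha * rng.standard_normal(len(t))
    return KinematicsSeries(t=t, omega_y=omega, alpha_y=alpha), label


def generate_cluster_trial(
    spec: TrialSpec,
    profile: GaitProfile,
    geom: Optional[ClusterGeometry] = None,
    accel_noise: float = 0.02,
    gyro_noise: Optional[float] = None,
    seed: Optional[int] = None,
) -> Tuple[ClusterSeries, KinematicsSeries, TrialLabel]:
    """Four-package cluster readings wrapping the rigid-body forward model.

    The trunk's angular state is taken from a noise-free kinematics
    trial about the transverse axis; per-channel Gaussian noise is added
    to every accelerometer and gyroscope channel.  Returns the cluster
    series, the noise-free ground-truth kinematics, and the label.
    """
    g = geom or default_geometry()
    clean_profile = replace(profile, noise_omega=0.0, noise_alpha=0.0, vibration_omega=0.0)
    kin, label = generate_trial(spec, clean_profile, seed=seed)
    rng = np.random.default_rng(
        (profile.seed if seed is None else seed) + 0x5EED
    )
    n = len(kin.t)
    a = np.empty((n, 4, 3))
    w = np.empty((n, 4, 3))
    a0 = np.array([0.0, 0.0, 9.81])
    for i in range(n):
        sample = rigid_body_forward_model(
            alpha_true=np.array([0.0, kin.alpha_y[i], 0.0]),
            omega_true=np.array([0.0, kin.omega_y[i], 0.0]),
            a0=a0,
            geom=g,
            t=float(kin.t[i]),
        )
        a[i] = sample.a
        w[i] = sample.w
    sigma_w = profile.noise_omega if gyro_noise is None else gyro_noise
    a += accel_noise * rng.standard_normal(a.shape)
    w += sigma_w * rng.standard_normal(w.shape)
    return ClusterSeries(t=kin.t, a=a, w=w), kin, label


def _apportion(n: int, mix: Dict[str, int]) -> Dict[str, int]:
    """Largest-remainder apportionment of n trials over the mix weights."""
    total = sum(mix.values())
    raw = {k: n * v / total for k, v in mix.items()}
    counts = {k: int(np.floor(r)) for k, r in raw.items()}
    short = n - sum(counts.values())
    order = sorted(mix, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:short]:
        counts[k] += 1
    return counts


@dataclass
class SyntheticTrial:
    subject: int
    kin: KinematicsSeries
    label: TrialLabel


@dataclass
class BenchmarkSet:
    """A reproducible labelled corpus for end-to-end metric tests."""

    trials: List[SyntheticTrial]
    profiles: Dict[int, GaitProfile]
    baselines: Dict[int, List[BaselineTrial]]
    seed: int

    def labels(self) -> List[TrialLabel]:
        return [tr.label for tr in self.trials]


def cohort_profile(rng: np.random.Generator, seed: int) -> GaitProfile:
    """Draw one subject profile from cohort-style ranges.

    Pulse amplitudes span the reported averaged-local-maximum range
    (19-46 rad/s^2); step frequency varies around the cohort cadence.
    """
    return GaitProfile(
        step_frequency=float(rng.uniform(1.75, 2.15)),
        omega_amp_1=float(rng.uniform(0.40, 0.60)),
        pulse_amplitude=float(rng.uniform(19.0, 46.0)),
        seed=seed,
    )


def generate_benchmark_set(
    n_trials: int = 627,
    mix: Optional[Dict[str, int]] = None,
    seed: int = 0,
    n_subjects: int = 18,
    noise: bool = True,
    trial_duration: float = 10.0,
    magnitude_scale: float = 1.5,
) -> BenchmarkSet:
    """Generate a benchmark corpus with the reference class mix.

    At the default n=627 the apportionment reproduces the reference
    composition exactly (179 perturbed / 448 ADL).  Trials are assigned
    round-robin to a cohort of subjects, each with its own profile and
    three calibration baselines.  Deterministic in ``seed``.
    """
    the_mix = dict(DEFAULT_MIX if mix is None else mix)
    counts = _apportion(n_trials, the_mix)
    master = np.random.default_rng(seed)
    profiles: Dict[int, GaitProfile] = {}
    baselines: Dict[int, List[BaselineTrial]] = {}
    for s in range(n_subjects):
        prof = cohort_profile(master, seed=seed * 1000 + s)
        if not noise:
            prof = replace(prof, noise_omega=0.0, noise_alpha=0.0, vibration_omega=0.0)
        profiles[s] = prof
        baselines[s] = [
            generate_baseline(prof, seed=prof.seed + 101 + j) for j in range(3)
        ]

    trials: List[SyntheticTrial] = []
    idx = 0
    for key in sorted(counts):
        for _ in range(counts[key]):
            subject = idx % n_subjects
            prof = profiles[subject]
            if key in PERTURBATION_CONTEXT:
                host = PERTURBATION_CONTEXT[key]
                duration = trial_duration if host == "walking" else 8.0
                onset = float(
                    master.uniform(duration * 0.35, duration * 0.65)
                )
                spec = TrialSpec(
                    task=host,
                    perturbation=PerturbationSpec(
                        type=key, onset=onset, magnitude_scale=magnitude_scale
                    ),
                    duration=duration,
                )
            else:
                duration = 8.0 if key in ("standing", "sit_to_stand") else trial_duration
                spec = TrialSpec(task=key, duration=duration)
            kin, label = generate_trial(
                spec, prof, seed=int(master.integers(0, 2**31))
            )
            trials.append(SyntheticTrial(subject=subject, kin=kin, label=label))
            idx += 1
    return BenchmarkSet(trials=trials, profiles=profiles, baselines=baselines, seed=seed)
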
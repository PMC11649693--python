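# Methods

`nearfall` implements an automated framework for detecting near-falls —
sudden losses of balance recovered by a neuromuscular response before
ground impact — from the trunk's angular kinematics about its transverse
(pitch) axis, and for distinguishing them from activities of daily
living (ADLs). This note records the model, the numerical choices, and
what the synthetic test bed does and does not establish.

## Sensing model

Two sensing routes produce the same pair of signals, the transverse
angular velocity ω_y (rad/s) and angular acceleration α_y (rad/s²):

1. **Inertial measurement cluster (IMC).** Four rigidly mounted
   accelerometer+gyroscope packages. For a rigid assembly, the package
   accelerations satisfy a_i = a_0 + α × r_i + ω × (ω × r_i), where r_i
   is the position of package *i* relative to package 0. Pairing each
   relative acceleration (stripped of the centripetal field) with the
   next arm vector gives a 3×3 linear system whose matrix has rows
   (r₁₀×r₂₀)ᵀ, (r₂₀×r₃₀)ᵀ, (r₃₀×r₁₀)ᵀ; solving it yields α directly,
   with no numerical differentiation. ω is the component-wise mean of
   the four gyroscope readings. The default geometry uses orthogonal
   arms of 0.08, 0.08 and 0.05 m. The system is solved per sample with
   `numpy.linalg.solve`; conditioning is validated once per geometry
   (condition-number cap 1e8). The sign convention of the arm vectors
   is fixed by the requirement that solving a forward-modelled sample
   recovers α exactly (verified to 1e-9 in the tests); the prose
   convention "from package i to 0" does not close the algebra.
2. **Single IMU.** One package measures ω_y directly; α_y must be
   obtained by a difference quotient, either central
   ((f[i+1]−f[i−1])/2Δt) or backward ((f[i]−f[i−1])/Δt). Boundary
   samples are marked unavailable (NaN) and trimmed, never padded, so
   no synthetic edge extrema enter the analysis. For white gyro noise
   of variance σ², the differenced acceleration carries noise variance
   σ²/(2Δt²) (central) or 2σ²/Δt² (backward) — at 100 Hz a two to four
   order-of-magnitude amplification that drives every difference
   between the routes reported below.

An optional zero-phase low-pass stage (2nd-order Butterworth, default
cutoff 20 Hz) is available for raw cluster channels and is off by
default and in all exactness tests.

## Detection framework

All rules are scaled by **personalised thresholds** calibrated from
three unperturbed walking trials per subject (≈1.4 m/s target speed):

* the averaged step frequency — the reciprocal of the earliest
  near-maximal peak (≥ 0.75 of the tallest) of the raw, non-demeaned
  autocorrelation of α_y. The earliest-near-maximal rule matters
  because lag quantisation of sharp touchdown content can make the
  second harmonic peak marginally taller than the fundamental. The
  value times 60 is comparable to a cadence in steps/min (the default
  synthetic cohort calibrates near 117 steps/min);
* per signal, the global maximum/minimum and the averaged local
  maxima/minima of the zero-crossing-segmented local extrema. Before
  averaging, noise-dominated magnitudes are excluded by a distribution
  monitor (five histogram bins of width 1 rad/s² / 0.05 rad/s up to
  ±5 rad/s² / ±0.25 rad/s; a quartile-outlier bin marks everything up
  to its edge irrelevant, never less than the ±2 rad/s² / ±0.1 rad/s
  noise clamp), and the touchdown-induced α maxima are isolated by
  raising a cutoff one bin width at a time until every gap between
  surviving maxima is a whole number of step periods within ±10%
  (up to 10% of gaps may violate, which tolerates isolated intruders
  while still rejecting systematic clutter; at most 20 iterations).
  Minima — and ω maxima, whose peaks are flat because their derivative
  vanishes there — are refined with exactly two cutoff iterations
  instead, since they are not locked to sharp gait events.

**Necessary condition (observation windows).** Local extrema of ω_y
beyond 1.15× the personalised global extrema are clustered (split at
gaps longer than one step period), each cluster extended by half a step
period per side, and kept only if α_y also holds an extremum beyond
1.15× its global bounds inside the extended interval. The onset is
refined to the sample immediately after the last α_y zero crossing
preceding the first triggering extremum; the offset to the zero
crossing after the last one, accepted only once all extrema of both
signals stay inside the ±1.15× band for one step period (otherwise the
window re-extends). Windows truncated by the record are flagged, not
dropped; overlapping windows merge. Raising the 1.15 ratio never
increases the window count.

**Sufficient condition (three-step analysis).** Per window:

1. *Periodicity versus correlated outliers.* Touchdown-type α maxima
   are isolated against the window's own dominant autocorrelation
   period with the same cutoff-scan used in calibration (scan step
   scaled to the window's magnitude range). Three or more repetitions
   of consistent magnitude — no maximum-versus-mean outlier among them
   — is direct evidence of a consciously performed activity: ADL.
   Otherwise, a max-versus-mean outlier (factor 1.5) in α_y whose
   spacing breaks the window's rhythm (nearest neighbour closer than
   half the median gap and than one step period), time-correlated
   (±0.15 s) with an ω_y outlier, is a balance-recovery response.
   The outlier subsets contain only *relevant* extrema — at least the
   averaged-local thresholds in magnitude — because the ordinary gait
   population (touchdown peaks plus one harmonic maximum per period)
   is bimodal enough to defeat the 1.5 factor otherwise.
2. *Frequency content.* The autocorrelation of the window extended by
   1.25 s is screened for coefficient peaks that are high-side quartile
   outliers; a flagged lag shorter than the step period that is not
   within 10% of an integer multiple of another peak's lag marks
   transient frequency content: recovery.
3. *Boundary outliers.* The window extended by four step periods per
   side is screened for a time-correlated (±0.15 s) outlier pair across
   the two signals; here the outlier subsets fall back to all
   supra-clamp extrema when fewer than two relevant extrema exist, so
   an isolated anomaly against quiet stance stands out. No pair: ADL.

The steps short-circuit: a step-1 verdict is final. Step 1 evaluates
periodicity before the outlier pair — an intact periodic pattern
spanning the window cannot coexist with a recovery response, and a
decaying recovery oscillation mimics spacing regularity but not
magnitude consistency, so the magnitude veto keeps the order safe.

**Attribution.** For each recovery window, the four step periods before
the onset are summarised by the mean relevant α maximum and the dominant
period, and compared (sum of absolute relative deviations, ties to
walking) against task references: walking = the calibrated thresholds;
running = walking × 4.1 in amplitude (the ratio of the reported
averaged global maxima for running versus baseline walking) and × 0.72
in period; standing = a 1 rad/s² amplitude floor (an interval with
fewer than two supra-clamp maxima is standing outright). The
perturbation type follows the sign of the dominant ω_y extremum in the
initial interval (half the window, capped at 0.25 s) under the
forward-pitch-positive convention: anterior during walking = trip,
posterior = slip; during standing, anterior/posterior loss of balance.
The convention is a configuration constant validated by an axis-flip
antisymmetry test.

**Metrics.** Trial-level sensitivity, specificity, PPV and F1 (a trial
is positive if any window is a recovery; surplus calls are tallied
separately), prevalence as the perturbed share of all trials, and the
Bayes extrapolation PPV(p) = se·p / (se·p + (1−sp)(1−p)) for judging
the detector at realistic daily-life prevalences.

## Synthetic test bed

Every deterministic signal component is an analytic (ω, dω/dt) pair, so
the single-IMU route sees the same events through its own filter; only
sensor noise is drawn per channel.

* **Walking**: ω_y harmonics at the step frequency (defaults 0.45,
  0.05, 0.10 rad/s; cohort fundamental drawn U(0.40, 0.60) — gait
  velocity extrema must clear the monitor's ±0.25 rad/s noise band, a
  premise of the framework itself) plus, per touchdown, a
  Gaussian-windowed velocity wavelet (carrier 5 Hz, envelope 0.05 s)
  whose derivative peaks at the pulse amplitude (default 32 rad/s²;
  cohort draw U(19, 46), the reported range of averaged-local maxima;
  per-step jitter 5%). Harmonic phases make all harmonic acceleration
  terms vanish at the touchdown instants, so the realised touchdown
  maxima are the generator's ground truth for the averaged-local
  threshold.
* **Noise**: white gyro noise (0.02 rad/s), white cluster-solution
  acceleration noise (0.5 rad/s², the value propagated from 0.02 m/s²
  accelerometer noise through the default geometry), and — decisive for
  the route comparison — *impact-locked vibration* noise in the gyro
  channel (0.04 rad/s per walking-scale impact, scaling with impact
  magnitude). Differencing amplifies the vibration into artefact
  extrema of near-touchdown magnitude at exactly the instants where
  genuine extrema live; the cluster's algebraic α does not inherit it.
  With this model the calibrated global-threshold deviation factors of
  the differenced routes come out ≈1.08 (central) and ≈1.28–1.31
  (backward) against the cluster, matching the reported 1.1 and 1.3 —
  the generator is calibrated against those reported factors, not
  against any detection outcome.
* **ADLs**: running (cadence ×1.35, amplitude ×4.1, carrier ×3 — more
  forceful heel strikes carry sharper content, which also keeps the
  velocity lobes commensurate with the harmonics), stairs (×0.9),
  sit-to-stand (sub-threshold velocity lobes from stance), standing
  (0.3 Hz sway), pick-and-drop (walking paused into stance around each
  event, a ±1.4× bend-velocity excursion, and a load-release jolt drawn
  U(0.65, 1.0)× the global reference whose clean-signal peak stays
  below the 1.15× detection band). ADL trials vary in intensity
  (U(0.85, 1.15)), emulating the range of speeds and vigour in the
  emulated protocol.
* **Perturbations** (trip, slip, anterior/posterior loss of balance): a
  sustained damped velocity oscillation (2.5 Hz, τ=0.25 s) plus an
  impact wavelet, both direction-signed and scaled (default 1.5×) to
  the profile's global references and masked to start at the onset; the
  ongoing gait pattern is transiently suppressed, as a real recovery
  response interrupts it. First lobes of the two signals peak within
  the ±0.15 s correlation interval by construction.
* **Benchmark**: 627 trials in the reference composition (74 trips, 16
  slips, 62 anterior and 27 posterior losses of balance; 168 walking,
  72 running, 82 stairs, 84 sit-to-stand, 42 pick-and-drop) assigned
  round-robin to an 18-subject cohort, three calibration baselines per
  subject; any other size is apportioned by largest remainder. Fully
  deterministic in one integer seed.

Problem sizes used throughout the tests: 10–12 s trials at 100 Hz,
627-trial benchmarks, 20-profile calibration sweeps, 1000-motion solver
round trips.

### What the synthetic results do and do not show

On this test bed the cluster route reaches trial-level sensitivity and
specificity of 1.00 with perturbation-type accuracy ≈0.98, and the
backward-difference route loses specificity and drops to ≈0.50
type/preceding accuracy (quiet-stance intervals read as walking once
noise artefacts mimic touchdown maxima). These numbers validate the *logic* of the framework
under its stated assumptions; they are not evidence about real
recordings, which contain soft-tissue artefact, sensor misalignment,
inter-subject waveform variety and mediolateral components that the
generator deliberately omits.

## Numerical choices and edge cases

* Quartiles use linear interpolation of order statistics at position
  (n−1)p+1; ties inside a zero-crossing segment resolve to the earliest
  time; a sample equal to zero belongs to the non-negative side of the
  sign map.
* Autocorrelation follows the raw summation definition (no mean
  removal, no per-lag renormalisation); a demeaning flag exists but is
  off everywhere.
* Degenerate inputs raise typed errors: identically zero signals
  (autocorrelation), fewer than 4 values (quartile test), fewer than 2
  points (max-versus-mean test), empty extrema sets (summary),
  histogram limits that cannot hold five bins, non-converging
  calibration (with the last cutoff in the message).
* Windows at record boundaries are clamped and flagged truncated.
* A recovery window whose initial interval holds no ω_y extremum keeps
  its recovery verdict with type `none`.

## Known limitations

* Only antero-posterior (pitch-axis) mechanics are modelled; mediolateral
  perturbations are out of scope.
* Calibration is global and static; re-running `calibrate` is the
  supported re-calibration path.
* The ADL templates are parameterised by amplitude and periodicity
  only; no musculoskeletal simulation is attempted.
* The central-difference route's threshold inflation depends on the
  vibration noise component: under purely white gyro noise at 0.02
  rad/s the smoothing loss of the central quotient approximately
  cancels its noise gain and the inflation factor sits at ≈1.0.
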
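# Methods

This note documents the models, estimators, defaults, and design choices
behind `gazestab`, and what the synthetic fixtures do and do not emulate.

## Coordinate and sign conventions

Angles are in degrees, time in seconds, accelerations in g.  Positive
rotation is toward the animal's dorsum for roll and pitch and toward its
left for yaw.  Video y-axes that increase downward are sign-inverted once,
during pixel-to-angle calibration (`Calibration.y_axis_down`), and nowhere
else.

## Eye kinematics

**Label averaging.** Eye position per frame is the mean of the eye-label
coordinates (four labels by default), which reduces independent tracking
jitter by √n.  Frames where any eye label falls below the likelihood gate
(default 0.8) are masked and linearly interpolated; masked gaps longer than
200 ms are left as NaN and reported instead — quick phases last ~24 ms, so
bridging long gaps would fabricate dynamics.  More than 50% masked frames
is treated as a failed recording.

**Body-motion subtraction.** `corrected = eye − (body − mean(body))`
removes any motion component shared by eye and body labels (breathing,
platform vibration) exactly, while the constant it introduces is cancelled
by the reference-relative angle conversion.

**Pixel-to-degree conversion.** The primary model treats the on-image
pupil displacement d (mm, via the mm/px index measured from the eye
diameter) as a chord of the rotating eyeball of diameter D:
θ = 2 asin(d/D).  The small-angle arc model θ = (2d/D)·(180/π) is available
(`angle_mode="arc"`); the two agree to <0.01% for d ≤ 0.01 D.  The chord
form was chosen as primary because it is exact for a rigid eyeball under
planar projection; the underlying trigonometric convention in tracking
studies is rarely stated, so both are exposed.

**Head orientation from acceleration.** For quasi-static tilts the gravity
component dominates and roll = atan2(ay, −az), pitch =
atan2(−ax, √(ay²+az²)) after a 5-sample moving average.  Yaw is not
observable from a static accelerometer (rotation about gravity); yaw head
angle must come from the platform command profile.  A warning is issued
when |a| deviates from 1 g by >20% on >10% of samples.

**Velocity.** Savitzky–Golay local-polynomial differentiation, window 7,
order 2 (70 ms at 100 Hz).  Passband attenuation grows as (f·w)²: ~0.5% at
1 Hz, ~1.8% at 2 Hz at 100 Hz sampling.  Endpoints use the filter's
one-sided fits.

**Latency alignment.** The oculomotor latency is estimated as the argmax of
the normalized cross-correlation of |velocity| over ±0.3 s after resampling
both traces to the finer time base, then removed by shifting the eye trace.
The estimate is quantized to one sample.

## VOR gains

Two complementary gains quantify compensation:

* **Position gain** = AUC(|eye|) / AUC(|head|) (trapezoidal integrals) over
  the **active-movement window**, after desaccading the eye trace and
  re-zeroing both traces at the window start.  Re-zeroing makes the
  estimate invariant to static offsets.  The active window is the first
  contiguous block of |v_head| above 5% of its peak (sub-50-ms dips
  bridged); taking the first block — rather than first-to-last crossing —
  keeps the window on the dynamic tilt and off the static hold and any
  return movement.
* **Dynamic gain** = median over slow-phase samples of |v_eye|/|v_head|,
  restricted to samples with |v_head| ≥ 20% of peak head speed, computed
  after latency alignment.  The median is robust to near-zero head-velocity
  samples; the floor removes the rest.  Alignment matters: with an
  oculomotor latency L comparable to the acceleration ramp, the unaligned
  sample-wise ratio mixes ramp samples against plateau samples and is
  biased low; aligning first makes the ratio constant (= gain) wherever the
  velocity profile is locally linear.  A classical two-point mode
  (displacement ratio between two explicit timestamps) is provided.

**Desaccading** replaces each quick phase with a linear bridge that
continues the local slow-phase velocity (mean slope of the adjacent slow
phases) and shifts all later samples to keep the trace continuous.
Bridging with the slow trend rather than holding flat keeps the cumulative
slow-phase trajectory unbiased even when quick phases occupy ~10% of the
rotation; with a perfect segmentation, inserting quick phases into a
fixture changes the position gain by well under 2%.

## Nystagmus segmentation

Quick phases move in the *same* direction as the head and much faster than
the compensatory slow phase.  A sample interval is a quick-phase candidate
when its velocity sign equals the head direction *and* its speed exceeds
`speed_factor` (default 3) × the median speed of slow-direction intervals;
candidate runs separated by <5 ms are merged and events shorter than 8 ms
are discarded.  Segmentation uses first-difference (per-interval)
velocities rather than the Savitzky–Golay estimator: 24-ms events span 1–4
samples at 100 Hz and a 70-ms smoother would smear them below threshold,
whereas first differences keep event boundaries exact on noise-free data.
Per-event statistics are duration = end − start, amplitude =
|angle(end) − angle(start)|, velocity = amplitude / duration.

## Synthetic-data generator

The generator is the package's test bed; its defaults are the study
conditions the estimators are validated against.

* **Head motion**: trapezoidal-velocity tilt (acceleration defaults 305.75
  / 915.73 °/s² for speeds ≤ / > 80 °/s, matching measured platform
  dynamics) to the commanded amplitude, optional static hold and mirrored
  return; closed-form piecewise-quadratic angle, so the commanded amplitude
  is met exactly.  Canonical protocols: 5.8° or 22.7° at 48.7 or
  112.94 °/s.  The trapezoidal profile is a modeling choice — only mean
  accelerations of the real platform are known.  The accelerometer signal
  is the rotated gravity vector plus 0.01-g noise.
* **VOR eye traces**: slow-phase eye velocity = −dynamic_gain × head
  velocity delayed by a latency L, with L solved by 1-D root search so the
  AUC-ratio estimator returns exactly the requested position gain on the
  noise-free trace.  Plane defaults: dynamic 0.77 / 0.60 / 0.69 and
  position 0.67 / 0.45 / 0.64 for roll / pitch / yaw.  Position gain above
  dynamic gain is infeasible in this model (delay only shrinks the eye
  AUC).  Default measurement noise 0.05°.
* **Nystagmus**: when eye eccentricity exceeds the orbit limit (default
  2°), a constant-velocity reset toward center is inserted with duration ~
  TruncNormal(0.024 s, 30% SD, bounds 0.5–1.5×) snapped to the sample grid
  and amplitude ~ TruncNormal(1.72°, 30% SD, same bounds); slow-phase
  velocity is suspended during the reset and unchanged elsewhere.  The
  full-rotation fixture (180° yaw at 137 °/s) uses a slow-phase gain of
  0.05: the quick-phase speed envelope (≈ 24–170 °/s given the truncation
  bounds) must exceed 3× the slow speed for any velocity-threshold
  segmenter to be able to separate the phases, which bounds the slow speed
  below ~8 °/s at this rotation speed.  Slow-phase gain during fast
  whole-body rotation is a free parameter of the fixture, not a measured
  quantity.
* **EMG**: motor-unit spike times from an inhomogeneous Poisson process,
  rate = baseline (2 Hz) + drive_gain (1 spike/s per °/s) × drive(t).
  The vestibular drive is the head speed during the dynamic tilt; the
  visual drive is a decaying transient (τ = 0.3 s, latency 0.15 s, initial
  rate ∝ stimulus speed); the combined condition sums the two — additivity
  is the *generator's* model of visuo-vestibular enhancement, and nothing
  in the analysis assumes it.  VES and VIS spikes come from substreams
  spawned from the seed, so a same-seed combined trial contains a superset
  of the vestibular-only spikes.  Ground-truth trains are thinned to a 2-ms
  refractory (motor-unit refractoriness); each spike becomes a biphasic
  2-ms derivative-of-Gaussian waveform (0.5 mV peak) in 0.05-mV Gaussian
  noise (SNR 10), digitized at 20 kHz.
* **EPSP trains**: instant rise to the per-pulse increment, exponential
  decay (τ = 0.05 s), linear superposition, 10 pulses at 10 Hz by default
  with a slightly depressing amplitude profile (3%/pulse from 1 mV), at
  10 kHz with 0.02-mV noise.  Stored ground truth is the per-pulse
  increment, not the superposed peak.
* **Swim coupling**: tail = sinusoid + noise; each eye = −k × tail delayed
  by 7 frames + independent noise.

What the fixtures do **not** emulate: eye-plant mechanics (the eye here
follows the commanded kinematics exactly), tracking dropouts and outliers
beyond Gaussian jitter, non-stationary EMG baselines, motor-unit waveform
variability and superposition cancellation, dendritic filtering or
conductance nonlinearity of EPSPs, and adaptation across trials.  Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated noise models, not robustness to every pathology of real
recordings.

## EMG quantification

Baseline = median of the pre-stimulus epoch (whole-trace median with a
warning when absent).  Noise scale = 1.4826 × MAD of the baseline-subtracted
pre-stimulus signal — robust to bursts.  Spikes are suprathreshold local
maxima of the rectified trace separated by ≥2 ms; the threshold default is
5 × the robust σ.  (A 4σ threshold admits a handful of noise peaks per
50 000-sample trial — about 3 expected from the Gaussian tail alone — which
is material when trials contain only tens of true spikes; at 5σ the
expected false count is ≪1 while 10σ waveforms remain far above threshold.)
The default analysis window runs from stimulus onset to the end of the
static tilt for trials with a vestibular component, and onset + 2 s for
visual-only trials; the response extent of real recordings motivates both,
and the window is exposed in the API.  Time-to-peak is measured on a
10-ms moving-average-smoothed rectified trace so a single noise sample
cannot define the peak.  Per-animal normalization divides each metric by
its per-animal, per-modality maximum (idempotent; all-zero groups are an
error).  Spike-density maps use 100-ms bins aligned at stimulus onset,
averaged over trials, divided by the maximum bin; an all-zero map is
returned unnormalized rather than dividing by zero.

## EPSP amplitudes

Later responses in a train ride on the decay of earlier ones, so raw
peak-to-rest distances overestimate them.  Each response's decay segment
(from its peak, after a 1-ms artifact blank, to the next pulse) is fitted
with A·exp(−(t−t_peak)/τ) + C by least squares.  Because a sum of same-τ
exponentials is itself a single exponential, extrapolating the previous
response's fit to the next pulse onset gives the exact superposed baseline
under the shared-τ model; the response's own fit is back-extrapolated to
its pulse onset, undoing the decay lost during blanking.  Amplitude_i =
(own fit at pulse i) − (previous fit at pulse i); pulse 1 is measured from
the pre-train baseline.  A response with no resolvable positive amplitude
is flagged missing (NaN), never zero.  Decays are fitted per response; a
shared-τ variant would be a natural extension but per-response fits make
no cross-response assumptions.  Single-exponential decay is assumed;
a double-exponential adds parameters the short inter-pulse segments cannot
constrain.

## Statistics

All test statistics are computed from their closed forms; p-values come
from the exact t/F distributions.  Grubbs: iterative two-sided screening at
α = 0.05 with critical value G = ((n−1)/√n)·√(t²/(n−2+t²)),
t = t_{1−α/(2n), n−2}, capped at removing 20% of the input (a safeguard
against runaway stripping of small samples).  Paired t: two-tailed, no
corrections.  One-way repeated-measures ANOVA: classical partition,
F = MS_treatment / MS_(treatment×subject), df (k−1, (k−1)(s−1)); sphericity
is assumed and no correction applied — recorded in the result metadata.
Pairwise follow-ups are paired t-tests with Holm step-down adjustment
(monotone, never below the raw p).  Lagged Pearson correlation shifts one
series by an integer frame count and correlates the overlap (df =
n_overlap − 2); the canonical eye-tail analysis uses a 7-frame lag.

## Problem sizes and numerical choices

The canonical validation runs use: single 30° rotations at 120 °/s, 100 Hz,
noise 0.05°, seeds 1–3 for the gain estimators; three-to-eight 180° yaw
rotations at 137 °/s for quick-phase statistics (~5 events each); 20 seeded
trial pairs for EMG spike recovery and the combined-vs-vestibular
comparison; 20 seeds for EPSP recovery; 10 000 replicates for the paired-t
type-I calibration.  Root searches (latency L) use Brent's method to 1e-6 s;
decay fits use bounded Levenberg–Marquardt (trust-region) with A ≥ 0 and
τ ∈ [1e-6, 10] s, and a fit is rejected as non-decaying when A collapses to
zero or τ hits its ceiling.  Degenerate inputs (constant traces, zero head
AUC, flat pre-stimulus noise, zero-variance differences) raise typed errors
rather than returning NaN.

## Known limitations

* Gravity-based orientation cannot observe yaw; yaw analyses need the
  platform command profile.
* The segmenter assumes quick phases are faster than the slow phase by the
  configured factor; at high rotation speeds with high slow-phase gain the
  two speed distributions overlap and no velocity threshold separates them.
* The latency model is a pure delay; real oculomotor dynamics add filtering
  that the position/dynamic gain pair only partially captures.
* Holm-adjusted pairwise tests after RM ANOVA assume the same pairing
  structure as the omnibus; unbalanced or incomplete designs are rejected,
  not imputed.
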
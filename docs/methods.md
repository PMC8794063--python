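# Methods

This note documents the model and analysis choices in `dynreach`: what is
assumed, which parameters matter, where the design was genuinely open and
what was decided, and what the synthetic-data tests do and do not show.

## Plant and observation model

Each Cartesian axis of the reach is simulated by an independent six-state
linear plant `x = [p, h, v, F_MC, F_E, p*]ᵀ` discretized by Euler
integration at δt = 10 ms. Cursor and hand positions both integrate the
velocity and coincide in the plant; they differ only in what the visual
channel is shown (cursor manipulations act on the visual observation, not
on the hand). The external force F_E is a step held constant within a
trial; from the controller's point of view it is an unknown constant state
to be estimated from feedback.

Feedback delays are modelled by state augmentation: the augmented state
stacks the current core state and its last δ_v copies (dimension
6·(δ_v+1) = 60 at defaults), the transition matrix shifts each lag block
down by one per step, and the two observation block-rows read the lag-δ_p
block (proprioception: hand position, velocity, muscle force, external
force, target) and the lag-δ_v block (vision: cursor position, velocity,
target). Unobserved coordinates appear as zero rows whose observation
components are pure sensor noise; they receive essentially zero Kalman
weight and are retained so each modality's block keeps the core-state
shape.

The estimator is a delay-compensating Kalman filter: the prior is
propagated through the forward model, and each modality's innovation
compares its observation against the prior at that modality's lag (in the
shift-register state this is exactly `K(y_t − H x̂_t)`). On no-vision
steps the visual innovation term is omitted entirely; the gains are not
recomputed (the experimental manipulation is a change of available
feedback, not of the controller).

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| m | 1.0 | kg | moving mass |
| G | 0.15 | N·s·m⁻¹ | viscous damping (elbow-like) |
| τ (muscle) | 0.066 | s | first-order muscle low-pass |
| δt | 0.010 | s | discretization step |
| δ_p | 5 steps | (50 ms) | proprioceptive delay |
| δ_v | 9 steps | (90 ms) | visual delay |
| N | 110 steps | (1100 ms) | horizon (perturbed-trial time limit) |
| σ | 0.066 | — | additive motor noise, covariance σ²BBᵀ |
| c∥ | 0.015 | — | signal-dependent motor noise SD per unit u |
| Σ_p | 10⁻⁵ | m², … | proprioceptive noise variance per coordinate |
| Σ_p/Σ_v | 2.3 | — | vision weighted ≈70% vs ≈30% |
| Σ_INTERNAL | 0.8×10⁻⁶ | — | prediction noise per augmented coordinate |
| R | 10⁻⁶ | — | control cost weight |

The orthogonal signal-dependent noise component (0.005) is retained in the
configuration but has no direction to act along in a per-axis scalar
control; it would matter only in a coupled two-dimensional plant.

### Cost schedule

The cost is quadratic in cursor-position error and control. With the
position penalty applied at every step and R = 10⁻⁶, the optimal
controller completes the 20 cm reach in ~200 ms — far faster than the
~700 ms human movements this model describes. The default therefore
applies the position penalty from step 70 (700 ms, the unperturbed
movement-time limit of the task) through the horizon, which paces the
reach to arrive at the target by ~700 ms and then stabilize; the noise-free
forward reach then crosses 3 cm at ~230 ms with a ~0.45 m/s peak velocity,
and the perturbed hand shows its peak lateral deviation ~250 ms after the
disturbance — all in the range of the human movements. Setting
`cost_hold_start=None` recovers the literal every-step penalty.

### Gain computation

Feedback and Kalman gains are computed by the coupled fixed-point
iteration for LQG with signal-dependent noise: a backward controller pass
given the Kalman gains (cost-to-go matrices on the state and on the
estimation error, with the control-dependent noise entering the gain
denominator) alternating with a forward estimator pass given the feedback
gains (unconditional second moments of the estimate, the error, and their
cross term). Convergence tolerance is 10⁻¹² on the largest gain change,
at most 500 iterations; at the defaults the iteration converges in 5
passes. In the delay-free, multiplicative-noise-free, internal-noise-free
limit the result matches independently coded Riccati/Kalman recursions to
10⁻⁸ (tested).

One approximation is inherited from this family of algorithms: the
controller pass assumes the estimation error and the estimate are
uncorrelated. The internal prediction noise violates that assumption
(it enters the estimate and the error with opposite signs, so
E[e x̂ᵀ] ≈ −Σ_INTERNAL), and a paired Monte-Carlo probe shows the computed
gains to be ~1% above the within-class optimum when Σ_INTERNAL > 0. With
Σ_INTERNAL = 0 — keeping delays, partial observability and
signal-dependent noise — the computed gains are a clear local cost
minimum under gain scaling. The local-optimality test therefore probes
that regime.

## Trial types

The disturbance onset is fixed at the step at which the noise-free
forward-axis hand crosses 3 cm travelled (reproducible, rather than
per-trial crossing detection). The step-force amplitude is calibrated —
the noise-free closed loop is linear, so one probe simulation suffices —
such that the noise-free peak lateral hand deviation equals 4.9 cm, the
experimental mean; it is exposed as a configuration knob, and all
percent-based quantities are invariant to it.

* `V_shift` replaces the visual observation's cursor-position and velocity
  components with the across-trial average of the mechanically perturbed
  (`PV_align`) simulation. Because the closed loop is linear with
  zero-mean noise, that average equals the noise-free trajectory, which is
  used directly (a finite noisy bank is available as an option); this
  avoids injecting Monte-Carlo jitter into every V-shift trial's visual
  stream. The condition's alignment point is the visualization onset: the
  first frame at which the planted cursor trajectory departs from rest.
* `PV_conflict` overrides the visual cursor position with
  `h + (−2a)/(1+exp(−(t+t_s)/τ_s))`, with (a, t_s, τ_s) calibrated by
  least squares on the PV-average excursion, and the visual velocity with
  that trajectory's analytic time derivative. The forward axis is
  untouched.
* No-vision conditions mask the visual observation from the disturbance
  onset onward.

Sigmoid calibration minimizes the residual between the perturbed-minus-
unperturbed displacement and the logistic over a window from 100 ms before
to 250 ms after the onset, with bounded least squares initialized at the
window-end displacement, the half-maximum time, and a 30 ms slope
constant; parameters are fitted independently per axis and disturbance
direction.

## Model analysis

Epoch responses are baseline-subtracted means of the lateral control
signal in half-open windows [90, 130) and [140, 180) ms after the
alignment onset — steps 9–12 and 14–17 on the 10 ms grid, samples 90–129
and 140–179 on the 1 kHz grid — against the baseline matched on
background-load context and vision availability. The additive comparison
reports `p + v`, its difference from the bimodal mean, and the percent
excess. Endpoint variability follows the 25-trajectories-per-cycle
protocol: the SD of lateral hand position at each timepoint within a
cycle, averaged over 1000 cycles (mean of per-cycle SDs, not a pooled SD).
Control-response onsets on model output use a threshold of 3 pre-onset
SDs of the condition−baseline difference (with a small absolute floor for
noise-free series) sustained for at least 10 ms. The sensitivity sweep
recomputes gains at every grid point of Σ_p/Σ_v ∈ {1.15, 2.3, 4.6} ×
δ_v ∈ {80, 90, 100} ms. The winsorized-trim utility replaces the lowest
and highest ⌈trim·n⌉ values by the nearest retained value (default trim
10%) for robust downstream statistics; hypothesis-testing machinery itself
is out of scope, and tidy epoch tables are exported instead.

Within the model, "response onset" has a one-step ambiguity: the control
is exactly at baseline through the sensory delay and departs on the
following step, so the first differing sample lies one 10 ms step after
the delay. Reported onsets use the last baseline-consistent sample.

## EMG pipeline

Filters are Butterworth, applied forward-backward (zero-lag) with
reflective padding of three times the filter order: EMG is band-passed
25–250 Hz (3rd-order sections, 6th-order polynomial), full-wave rectified,
then low-passed at 50 Hz (6th order); kinematics are low-passed at 20 Hz
(6th order). Small negative values after the final low-pass are retained.
Each muscle is normalized to its mean activity over the 100 ms preparation
window on trials where it counters the background load (extensor loads:
posterior deltoid and lateral triceps; flexor loads: pectoralis and
brachioradialis), and ΔEMG subtracts the baseline average matched on load
sign and vision availability. Trials are excluded when (1) the
preparatory mean exceeds the across-trial mean by 3 SD, or (2) a sample
within ±10 ms of the disturbance onset deviates from the trial median by
more than 10 median absolute deviations — the deviation form rather than a
raw amplitude test, since rectified tonic EMG has a large positive median.
Visual alignment adds the logged display latency plus a fixed 17 ms
refresh contribution to the command time; visual-only responses can be
scaled by the PV/V cursor-shift ratio over the first 90 ms after the
visualization onset.

ROC onsets operate on per-participant trial-averaged traces (trial-level
analysis available behind a flag), smoothed with a zero-lag 5 ms moving
average, with the AUC computed at every millisecond. The threshold time
is the start of the first run of 10 consecutive ms at AUC ≥ 0.75 (or
≤ 0.25; the side is recorded) — with one robustness addition: the run must
persist, i.e. the mean AUC over the following 50 ms must remain beyond
the threshold. The addition is needed because the null AUC between two
groups of ~13 traces is a rank statistic whose chance excursions do not
shrink with signal quality and occasionally sustain 10 ms. The knee walks
back from the threshold to the last 0.50 crossing and is refined to the
nearest preceding local extremum (ties toward the later time); the OLS
slope of the rise segment is reported, and the fitted line's extrapolated
0.50 crossing substitutes only when the AUC hovered beyond 0.50
throughout. Two intrinsic error sources remain and are visible in the
recovery studies: the zero-lag filter chain smears sharp onsets a few ms
backward, and a chance pre-onset stretch of AUC > 0.5 adjacent to the
real rise lengthens the walk in a minority of runs (median recovery error
is ~4–6 ms; isolated runs land 20–60 ms early).

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
muscle biophysics. Kinematics come from the model simulator at 10 ms,
cubic-spline upsampled to 1 kHz (synthetic-only; real data are sampled at
1 kHz natively), with a 100 ms hold prepended, condition-appropriate
cursor manipulations applied, and white measurement noise added. EMG is
an amplitude-modulated band-limited carrier: `tonic × (1 + response)`
multiplying the absolute value of 25–250 Hz Gaussian noise, which
exercises the band-pass/rectify/low-pass chain realistically. The
response kernel is a log-normal burst peaking 30 ms after its onset
(rising over ~20 ms, decaying to half by ~57 ms), excitatory for agonists
and inhibitory (floor-clipped) for antagonists, with onsets at the
proprioceptive (50 ms) or visual (90 ms) latency after the respective
disturbance events. Display latencies are drawn per trial
(logged-latency mean 26.4 ms, SD 0.86 ms, plus the fixed 17 ms refresh,
reproducing the experimental 43.4 ± 0.9 ms total). Trial counts follow
the experimental layouts (400 per participant in experiment 1, 250 in
experiment 2) and planted outliers of both exclusion classes are injected
with full ground truth.

What passing tests show: every analysis stage recovers its planted ground
truth at the stated tolerances under this noise structure. What they do
not show: performance on real EMG (electrode artifacts, nonstationary
tonic drift, crosstalk, participant idiosyncrasies are not modelled), and
the generator's subadditivity is whatever the model produces — the EMG
generator plants configured amplitudes and does not independently encode
multisensory integration.

## Numerical choices and degenerate inputs

Gain iteration: tolerance 10⁻¹² on the max gain change, 500-iteration cap,
non-convergence flagged but gains returned. Simulation raises with the
step index on NaN/divergence. Masked observations are recorded as absent
(NaN), never zero-filled. Zero delays collapse the augmentation to the
core system exactly. The winsorizer uses a stable argsort so ties keep
their original order. Epoch windows are half-open to avoid double-counting
boundary samples across adjacent windows.

## Limitations

* One-dimensional per-axis dynamics; no joint-space arm model, muscle
  geometry, or inter-axis coupling (the orthogonal motor-noise component
  is consequently inert).
* The absolute control-signal scale depends on the calibrated disturbance
  amplitude; only percent-based comparisons are scale-free.
* The gain computation is exactly optimal within its policy class only
  without internal prediction noise (see above); with it, gains are ~1%
  conservative relative to the simulated optimum.
* The ROC knee has an irreducible early-detection tail driven by the rank
  statistic's null fluctuations; median onset-recovery accuracy is the
  meaningful figure.
* The sigmoid fit window (−100 to +250 ms) assumes the disturbance-locked
  excursion is complete within 250 ms; slower plants would need a wider
  window.
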
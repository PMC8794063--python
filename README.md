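# dynreach

Dynamic Bayesian multisensory integration in online reaching control.

`dynreach` implements a delay-augmented linear-quadratic-Gaussian (LQG)
model of goal-directed reaching in which proprioceptive and visual feedback
arrive through separate, differently delayed channels, together with the
analysis pipeline needed to quantify its predictions and to process the
kind of data such experiments produce (1 kHz kinematics and surface EMG
from cursor-perturbation reaching tasks). It is written for computational
motor-control researchers who want to simulate, analyze, or test against
this class of model.

## The model

One axis of the reach is a six-state linear plant
`x = [p, h, v, F_MC, F_E, p*]ᵀ` (cursor position, hand position, velocity,
controlled muscle force, external force, target), discretized at
δt = 10 ms:

```
m v̇ = −G v + F_MC + F_E        τ Ḟ_MC = u − F_MC        Ḟ_E = 0
```

with m = 1 kg, viscous damping G = 0.15 N·s·m⁻¹, muscle time constant
τ = 66 ms. Motor noise has an additive part (σ = 0.066, entering through
the muscle row) and a signal-dependent part with SD 0.015·|u|. Sensory
delays are handled by stacking past states into a shift register of
dimension 6·(δ_v + 1): proprioception reads hand position, velocity, both
forces and the target at a 50 ms lag (Σ_p = 10⁻⁵·I); vision reads cursor
position, velocity and the target at a 90 ms lag (Σ_p = 2.3 Σ_v, i.e.
vision weighted ~70%). State estimation is delay-compensating Kalman
filtering — each modality's feedback is compared against the forward-model
prior *at that modality's lag* — with internal prediction noise
Σ_INTERNAL = 0.8×10⁻⁶. Control is `u_t = L x̂_t`, with L and the Kalman
gains computed offline by the coupled estimator/controller iteration for
LQG with signal-dependent noise, minimizing
`J = Σ_t (p_t − p*)² + R u_t²` with R = 10⁻⁶.

The emergent prediction is **subadditivity**: because proprioception has
already updated the state estimate (including the cursor estimate, through
the forward model) by the time visual feedback arrives, the corrective
response to a combined mechanical + visual disturbance is *smaller* than
the sum of the responses to each disturbance alone — vision contributes
little when it is congruent with proprioception, yet remains potent when
the two conflict.

Five trial types are built in: baseline reaching with and without cursor
feedback, a mechanical disturbance without vision (`P_nov`), a visual-only
disturbance in which the cursor follows the average mechanically perturbed
trajectory (`V_shift`), the combined disturbance (`PV_align`), and a
conflict condition in which the cursor moves opposite to the hand with a
sigmoid shift of amplitude −2a (`PV_conflict`).

The package also implements the experimental analysis chain: zero-lag
Butterworth filtering (EMG 25–250 Hz band-pass, rectification, 50 Hz
low-pass; kinematics 20 Hz low-pass), preparation-window EMG
normalization, vision- and load-matched baseline subtraction (ΔEMG),
outlier-trial exclusion, display-latency correction, V1/V2 epoch
quantification (90–130 / 140–180 ms), and ROC-based response-onset
detection (AUC per ms, 0.75-for-10-ms rule, knee regression to the last
0.50 crossing), plus a synthetic-experiment generator with full ground
truth for end-to-end validation.

## Worked example

```python
from dynreach import ReachingModel, additive_comparison, EpochSummary
from dynreach.analysis import epoch_table

results = ReachingModel().fit()          # solve feedback + Kalman gains
print(results.summary())

table = epoch_table(results, n_trials=2000, seed=202)
print(table.to_string(index=False))
```

```
Delay-augmented LQG reaching controller
============================================
horizon N               110 steps (1100 ms)
augmented dimension      60
prop. delay               5 steps (50 ms)
visual delay              9 steps (90 ms)
noise ratio Sp/Sv        2.30
converged              True in 5 iterations (max gain delta 0.00e+00)
peak |L|                  853.3
peak |K|                 0.9347
condition epoch   mean     se  n_trials
 PV_align    V1 7.0264 0.0054      2000
 PV_align    V2 8.3123 0.0073      2000
    P_nov    V1 7.0629 0.0051      2000
    P_nov    V2 8.3161 0.0064      2000
  V_shift    V1 0.1185 0.0057      2000
  V_shift    V2 1.0206 0.0075      2000
```

Each row is the baseline-subtracted mean lateral control signal (N) in
one response epoch. Reading the V1 epoch: the combined-disturbance
response (7.03 N) is *less* than the mechanical-only plus visual-only sum
(7.06 + 0.12 = 7.18 N) — a 2.2% additive-model excess, the subadditivity
signature. In V2 the excess grows to ~12% because the visual-only
response (1.02 N) has become substantial while the combined response has
not grown to match. Noise-free runs place the control-response onset one
step after 50 ms (proprioceptive delay) for mechanical disturbances and
one step after 90 ms (visual delay) for visual ones, and the endpoint
variability protocol (25 trajectories × 1000 cycles) shows the final-time
lateral SD roughly doubling when cursor feedback is removed.

A command line mirrors the library:

```bash
dynreach simulate --condition PV_align --n-trials 25 --seed 1 --out sims/
dynreach analyze-model --n-trials 1000 --seed 1 --out analysis/
dynreach sweep --n-trials 500 --seed 1 --out sweep.csv
dynreach synth --experiment 1 --n-participants 2 --seed 1 --out data/
dynreach analyze-emg --experiment data/ --out emg/
dynreach reproduce --seed 1 --out results/
```

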
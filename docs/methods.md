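# Methods

This note documents the models, parameter choices and numerical decisions
behind `emgrehab`, and what the simulation does and does not establish about
real training systems.

## Signal model and synthetic EMG

The generator emulates a consumer thigh-band whose "raw" stream is already
rectified and low-pass filtered on-device: per channel,
`y_c(t) = max(0, bias_c + gain_c · a(t) + ε)`, `ε ~ N(0, noise_sd²)`, where
`a(t)` is the ground-truth activation in [0, 1]. Units are arbitrary device
units; every downstream computation is scale-invariant after calibration, so
no absolute amplitude is assumed. The defaults — `bias = 1.0`, `gain = 4.0`,
`noise_sd = 0.5`, 8 channels at 200 Hz — give visibly noisy raw traces from
which calibration is still recoverable, the regime the system is designed
for. Each channel owns an independent generator spawned from a master seed.

What this model deliberately omits: motor-unit physiology, interference
patterns and unrectified waveforms; electrode lift-off, motion artifact and
crosstalk; slow drift, fatigue-induced spectral shifts, and day-to-day
electrode placement variability. Passing tests therefore demonstrate the
correctness and robustness of the *processing pipeline* under a controlled
envelope-plus-noise model, not clinical performance on human sEMG.

## Kalman filtering

The envelope is modeled as locally constant (identity state transition), so
the per-channel filter is scalar with process noise `Q = 1e-4` and
measurement noise `R = 0.59948`, fixed for all channels and subjects. Because
the covariance recursion ignores the data, `P` converges monotonically to the
fixed point `P_p* = (Q + √(Q² + 4QR))/2` and the filter becomes the
exponential smoother `X_k = X_{k−1} + KG*(Y_k − X_{k−1})` with
`KG* = P_p*/(P_p* + R) ≈ 0.012832`. At 200 Hz this single-pole response
attenuates strictly at every frequency above DC (−8.4 dB at 1 Hz, −13.9 dB at
2 Hz) and implies an envelope group delay of roughly `(1 − KG*)/KG*` samples
(~0.38 s at low frequency); the measured cross-correlation lag on burst
traces is ~250 ms, dominated by the envelope term.

Initialization is not dictated by the filter equations; we seed
`X0 = first measurement` and `P0 = R`, which avoids a start-up transient from
zero and is scale-free. Filtering precedes channel averaging, matching the
"mean of the filtered channels" control signal; since the filter is linear
and time-invariant with shared `(Q, R)`, the two orders are identical (a test
asserts this to 1e-10). The degenerate gain at `P_p = R = 0` is defined as 1;
it is unreachable under validated parameters. All arithmetic is double
precision.

## Calibration

`Bias` is the *mean* of the relaxed envelope (an unbiased estimate; the
downstream clamp absorbs sub-bias noise). "Sustained for at least 1 s" is
operationalized as the maximum over all 1 s sub-windows of the within-window
minimum — a literal reading with an obvious brute-force oracle, isolated in
`estimate_mve` so a sustained-mean or percentile variant is a one-line swap.
Calibration fails with `InsufficientSignalRangeError` when
`MVE − Bias ≤ 3 × rest SD`: with no voluntary range clearly above the noise
floor, proportional control would amplify noise, which is the unsafe case.

## Servo cascade and plant

The published architecture (proportional mapping → PD position loop → PID
velocity loop → motor) does not include numerical gains, so all controller
and plant constants here are this package's own: `pos_kp = 8 s⁻¹`,
`pos_kd = 0.05` (derivative on measurement), velocity PID `1.0/5.0/0.0` with
integrator clamp ±200 deg/s, speed limit 120 deg/s, plant time constant
50 ms, integration step `dt = 5 ms` (200 Hz, matching the EMG rate). They
were chosen once to give a stable loop whose desired-vs-actual lag is on the
order of 100–200 ms — the qualitative regime of cable-driven knee hardware —
and are exposed in config, not claimed as measured values. The plant is a
first-order velocity tracker integrated by explicit Euler; at `dt/τ = 0.1`
the integration error is negligible relative to the closed-form step response
(tested). Software limits pin the angle at [0°, 54°] during training;
simulated overtravel switches cut power at the mechanical stops
[−10°, 110°]; an emergency stop freezes the joint until reset. Safety
outcomes are returned as state, never exceptions, because they are normal
operating conditions for the loop around them.

The mapping clamps at the effort cap rather than rescaling (MVE and anything
above the 60% level both command 54°); the alternative reading — rescaling so
MVE→54° — is isolated behind `emg_to_angle` if ever needed.

## Game

The difficulty schedule interpolates the printed endpoints (gap 300→190 px,
speed ×1→×2.5, frozen above score 100) *linearly* in score; the original
curve shape between the endpoints is not recoverable from text, and the
schedule is one pure function so another shape is a one-line swap. Screen
480×800 px, pipe width 80 px, spacing 320 px, base speed 120 px/s, margins
60 px, 50 Hz tick, bird station at 0.2 × width, post-resume grace distance of
one pipe spacing: none of these are published; all live in `GameConfig`.
Collision uses axis-aligned bounding boxes; the y axis points up from the
bottom. Audio/haptics are events in the log, not rendered output. The whole
game is deterministic given (seed, input trace).

## Virtual subject and sessions

The subject computes the activation that would center the bird in the next
gap (the inverse of the altitude and mapping functions: mid-screen gap → 27°
→ activation 0.30), then pursues it with a first-order lag
(`pursuit_time_constant`, default 0.25 s), a reaction delay (0.15 s) and
multiplicative Gaussian noise (5%). These three knobs order subjects by
skill; the package asserts that ordering (better parameters → higher median
score), which is the honest property-level substitute for human learning
curves that no simulation of this kind can reproduce numerically. An
optional per-block decay of the noise models practice effects and is off by
default.

Sessions run calibration then 10 blocks per leg with 30 s recorded rests,
auto-resuming each life after a 1 s hover in place of the space-key press.
Control runs at 200 Hz and the game at 50 Hz with zero-order hold of the
joint angle. Each block carries a 120 s wall-time watchdog so that an
arbitrarily good subject cannot extend a block without bound; block
activation time and mMAL are computed over flying time only, consistent with
"active therapy" time (hover pauses and rests excluded). Session logs contain
simulated times only — no wall-clock timestamps — so a session is
byte-identical JSON given the same master seed.

## Problem sizes and tolerances

Test and acceptance workloads use sizes chosen for tight feedback loops:
filter-oracle comparisons on 1e5 random samples at 1e-12; steady-state
covariance against the quadratic root at 1e-10; filter-delay properties over
50 seeds of 30 s, 3-burst traces; calibration recovery over 100 seeds (5%
relative error in ≥ 95 runs); skill ordering over 20 seeds of single 30 s
blocks. Cross-correlation lags are reported on the 5 ms sample grid, so
lag assertions allow one-sample slack.

## Known limitations

* The envelope-plus-noise EMG model cannot validate filter behavior on real
  interference-pattern sEMG or on pathological (e.g. spastic) activity.
* Controller/plant constants are plausible artifacts, not system
  identification; tracking RMSE and lag values produced here characterize
  this simulated loop only.
* The virtual subject is a control-theoretic stand-in; scores and activation
  levels it produces support relative comparisons (between parameter sets,
  seeds, or code changes), never claims about patients.
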
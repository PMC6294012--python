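# Methods

## System overview

The simulated system is a 20 × 1 slice of a passive memristive crossbar: 20
input rows, each driving one memristor, all feeding a single output column
connected to a leaky integrate-and-fire (LIF) neuron. Input "neurons" place
pre-synaptic voltage pulses on the rows; when the LIF neuron fires it places a
post-synaptic pulse on the column and is refractory while it plays out. Other
columns of a real array are grounded and carry no learning signal, so a
multi-column experiment is simulated as independent single-column runs.

## Pulse waveforms (`memstdp.waveforms`)

Pulses are piecewise-linear `(duration, v_start, v_end)` segment lists,
evaluated right-continuously at segment boundaries (a voltage step takes the
later segment's value). Two printed variants are reproduced verbatim:

| pulse | segments (ms @ V) | total |
|---|---|---|
| pre, main | 5: 0→0.45, 7: 0.63, 1: 0.63→−0.4, 20: −0.4, 5: −0.4→0 | 38 ms |
| post, main | 5: −0.15→0.65, 23: 0.6, 1: 0.6→−1.15, 22: −1.15, 5: −1.15→−0.15 | 56 ms |
| pre, characterization | 5: 0→0.63, 10: 0.63, 2: 0.63→−0.54, 20: −0.54, 5: −0.54→0 | 42 ms |
| post, characterization | 5: 0→0.6, 23: 0.6, 2: 0.6→−0.5, 22: −0.5, 5: −0.5→0 | 57 ms |

Two printed oddities in the main protocol are reproduced rather than
smoothed: the pre ramp ends at +0.45 V while the following plateau is
0.63 V (a genuine step), and the post segments sum to 56 ms although the
protocol text quotes 57 ms; we use the segment sum. The −0.15 V post
baseline (a convenience of the analogue neuron) is applied to the column
only while a post pulse is scheduled; otherwise the column sits at virtual
ground.

The voltage across a device is `v_row − v_col`. A lone pre pulse spans
[−0.4, +0.63] V, a lone post pulse puts [−0.65, +1.15] V across the devices
of its column; overlapping pulses reach −1.0 V (pre tail over post plateau)
and +1.78 V (pre plateau over negative post plateau).

## Memristor model (`memstdp.memristor`)

Conductance `G ∈ [G_min, G_max]`, with threshold-gated exponential switching
that saturates toward the range edges:

* set, for `v ≤ −v_set`:  `dG/dt = +k_set · e^((|v|−v_set)/v0_set) · (G_max−G)/(G_max−G_min)`
* reset, for `v ≥ +v_reset`: `dG/dt = −k_reset · e^((v−v_reset)/v0_reset) · (G−G_min)/(G_max−G_min)`

This functional form is a modelling choice anchored to the qualitative
description of the devices (quasi-DC exponential switching that saturates in
time); alternative laws can be swapped in behind the `step_device` contract.

Defaults: `G_min = 2 µS`, `G_max = 60 µS`, `v_set = 0.8 V`,
`v_reset = 1.4 V`, `v0 = 0.1 V`. The thresholds sit mid-way inside the only
admissible windows: they must exceed the largest lone-pulse voltages
(0.63 / 1.15 V) so isolated pulses never disturb a device (half-select
safety), and stay below the overlap voltages (1.0 / 1.78 V) so overlapping
pulses can switch it. Reset is assigned the larger-magnitude overlap
combination, consistent with reset thresholds being larger in magnitude than
set thresholds in the physical devices.

`k_set = 0.17`, `k_reset = 0.15 µS/ms` are calibration constants, not
measured values: they were chosen once so the nominal device's STDP window at
the 16 µS operating point peaks near +100 % (potentiation) and −50 %
(depression) — the middle of the 50–200 % band the pulse amplitudes were
designed to produce. The measured window with these defaults peaks at +95.8 %
/ −50.0 %, is positive for small positive lags, negative for lags of −45 to
−20 ms, and identically zero once the pulses no longer overlap (lags outside
(−56, 38) ms).

Because the rate law is linear in `G` at fixed voltage, `step_device`
advances each step with the exact exponential solution of the within-step
ODE (the voltage is sampled at the step start). This keeps the stepper
within 1 % of a 10 µs explicit-Euler reference and makes dt-refinement
differences negligible; a plain Euler increment at dt = 0.5 ms would not meet
the 1 % convergence requirement under the 1.78 V reset drive.

**Variation.** Device-to-device variation is sampled as independent Gaussian
relative perturbations (defaults: 10 % on thresholds and rate constants, 5 %
on the dynamic-range edges), with thresholds clipped to preserve half-select
safety. Larger-threshold devices produce smaller updates at fixed lag, the
dominant variation effect in the hardware.

**Tuning.** `tune_conductance` is an idealized write–verify loop: fixed-width
(1 ms) set/reset pulses whose over-threshold amplitude starts at 0.05 V,
grows by 0.02 V while the error sign persists (capped at 0.5 V), and restarts
small on a sign flip; reads are noiseless direct state access
(instrumentation noise is out of scope). Every experiment begins with all
devices tuned to 16 µS, the middle of the dynamic range.

**STDP window measurement.** For each lag the device is re-tuned to 16 µS,
one pre and one post pulse are applied at that lag, and the device is
integrated under their difference voltage at 0.1 ms; reported as ΔG/G₀ in %.

## LIF neuron (`memstdp.neuron`)

`C dU/dt = I_in − U/R_L` with `C = 0.1 µF`, `R_L = 900 kΩ` (τ = 90 ms),
integrated by exponential Euler (exact for piecewise-constant current; the
zero-input decay reproduces `U₀·e^(−t/τ)` to machine precision). The
analogue front-end (op-amp stages, variable resistors, bias voltages) is
abstracted into `current_gain` (default 1) and the firing threshold.

`u_threshold = 3.0 V` is calibrated by construction: four simultaneous
spikes through 16 µS synapses peak at ≈3.5 V (fire), three at ≈2.6 V, two at
≈1.75 V (no fire). The value sits near the top of that window deliberately,
so that sub-coincidence activity — three inputs at the operating point, or a
lone potentiated synapse near nominal G_max (peak ≈3.3 V) — cannot fire what
is meant to be a coincidence detector. The pre pulse's negative tail
contributes negative current; no rectification is applied.

On firing, the post pulse starts at the crossing step, the membrane resets,
and the neuron is frozen at reset for `max(refractory, post duration)`
(default 56 ms); threshold crossings while a post pulse is active are ignored
(one waveform generator).

## Spike protocol (`memstdp.protocol`)

Frames of 840 ms, ten frames per epoch. Synchronized rows spike once per
frame at `reference_phase` (default 0) plus per-row uniform jitter on
`[0, t_jitter_max]` (one-sided by default; whether the hardware jitter was
signed is not stated, so `signed_jitter` exposes the alternative). Noise
rows spike with probability `p_spike` per frame (Bernoulli, at most one
spike per row per frame) at per-row staggered reference phases — 64 ms after
the synchronized phase, 15 ms apart (span 64–274 ms for 15 noise rows) —
plus a uniform offset on `[0, offset_max]` and jitter.

The staggered layout is a reconstruction (the original layout lives in
supplementary material unavailable here) constrained by four facts: at zero
offset the raster must be essentially non-overlapping and trivially
separable; at large offsets (≥ ~216 ms) all 15 noise spikes must be able to
coincide by chance; every pulse must end inside its own frame at the largest
printed offset (offset 500: 274 + 500 + 5 + 38 = 817 ≤ 840), which
`ProtocolConfig.validate` enforces and which also guarantees same-row pulse
instances never overlap; and noise-triggered post spikes must not
systematically land 17–46 ms before the next frame's synchronized event,
where they would depress the whole learned pattern at once.

Randomness: one sub-stream per (epoch, frame) derived from the session seed,
with fixed-shape per-row draws inside the frame — extending a session never
changes earlier frames.

`expected_rate = p_spike / frame_duration`: 1.19 Hz at `p_spike = 1`,
0.238 Hz at 0.2.

## Simulator (`memstdp.simulator`)

Fixed step `dt = 0.5 ms` (dt must divide the frame). Conductances change
only while a post pulse is active (half-select safety), so between post
pulses the membrane follows a linear recurrence with constant weights; the
engine evaluates it in vectorized blocks and locates the first threshold
crossing in closed form, dropping to per-step device updates only inside
post-pulse windows. The suite verifies this engine bit-for-bit (fire times)
and to 1e-8 µS (trajectories) against a brute-force per-step loop composed
of the public scalar operations. Identical configs and seeds give
bit-identical results; halving dt moves epoch-end conductances by < 1 %.

Conductances are read out at each epoch boundary, after any in-flight post
pulse has completed; if pulses extend past the nominal session end the
simulation runs until they finish.

## Reporting (`memstdp.reporting`)

Group summaries are arithmetic means per epoch (plus the all-device mean and
total); `detection_success` is a strict inequality between the final-epoch
synchronized and noise means (ties fail, conservatively);
`relative_change` is `(G_end − G_0)/G_0` per row; `first_crossing_epoch`
gives the time-to-discrimination used in the noise sweep.

## Problem sizes used in the checks

Empirical rate checks use 10⁴ generated frames per configuration. The
two-pattern learning property uses ten seeds of 60-epoch runs
(switch at epoch 30, `p_spike = 0.2`, jitter 5 ms, offset 500 ms, 10 %
threshold variation; ≈ 2 s per run). The noise-sensitivity sweep uses ten
seeds × four offset conditions (0/27/216/432 ms) of 20-epoch runs. The
STDP-window checks use a 41-point lag grid spanning ±100 ms with re-tuning
per point.

## What the generator does and does not emulate

The synthetic sessions reproduce the frame/epoch structure, the synchronized
and Bernoulli-noise roles, jitter, offsets, and the two-pattern switch. They
do not emulate: rate-coded inputs or Poisson trains (at most one spike per
row per frame), analogue DAC non-idealities, read noise in tuning, crossbar
parasitics (wire resistance, sneak paths), or filament-level device physics.
Passing tests therefore demonstrate the learning dynamics of the idealized
model, not quantitative agreement with any particular physical crossbar —
hardware trajectories are not bit-reproducible and the corresponding checks
are property-based (selectivity, ordering, sign structure) rather than
numeric.

## Known limitations

* With fixed-amplitude spikes, a neuron threshold cannot simultaneously
  admit four coincident 16 µS inputs (peak ≈3.5 V) and exclude a lone
  synapse at the top of its dynamic range (≈3.3 V, higher for high-G_max
  samples). After a pattern switch, the retired pattern's saturated synapses
  therefore fire the neuron on their own noise spikes, which slowly drags
  uncorrelated synapses upward — the in-model analogue of the random
  noise-driven post spikes and conductance jumps seen in hardware. The
  two-pattern property is robust to it (≥ 8/10 seeds) but individual seeds
  can fail when this drift is strong.
* Depression requires lags of about −46 to −17 ms; lags just below zero
  still potentiate (the pre tail overlaps the post plateau). This is a
  geometric property of the rectangular pulse pair, not a bug.
* The switching-rate constants are calibration targets, not measurements;
  absolute conductance trajectories (e.g. how fast synapses saturate) should
  not be compared quantitatively with any specific device batch.
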
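# memstdp

Simulation of **spike-timing-dependent plasticity (STDP) learning of
coincidence detection** in a spiking neural network whose synapses are
passively integrated (0T1R) metal-oxide memristors in a crossbar and whose
output is an analogue leaky integrate-and-fire (LIF) neuron.

The package is for computational-neuroscience and neuromorphic-hardware
researchers who want to reproduce and explore, entirely in silico, how a
single LIF neuron driven through 20 memristive synapses learns to fire
selectively on temporally synchronized inputs amid uncorrelated noise — and
how device-to-device variation degrades that learning.

## The model

**Neuron.** The membrane potential `U` (referenced to rest) obeys

```
C dU/dt = Σᵢ Gᵢ · Vᵢᵖʳᵉ(t) − U / R_L
```

with `C = 0.1 µF`, `R_L = 900 kΩ` (so `τ = R_L·C = 90 ms`). The input current
is the dot product of the row voltages and the synaptic conductances `Gᵢ`.
On reaching threshold, the neuron fires a post-synaptic pulse onto the
crossbar column, resets, and is refractory while the pulse plays out.

**Synapses.** Each memristor's conductance lives in a dynamic range
`[G_min, G_max]` and switches only when the voltage across it exceeds
polarity-dependent thresholds, with exponential voltage acceleration and
saturation toward the range edge. STDP is not programmed — it *emerges* from
pulse overlap: the pre spike (5 ms ramp to +0.45 V, 7 ms 0.63 V plateau, then
a −0.4 V tail, 38 ms total) and the post spike (+0.6 V plateau then −1.15 V
plateau) only produce switching-capable voltages (−1.0 V set, +1.78 V reset)
where they overlap, giving the classic asymmetric window

```
ΔG = f_STDP(t_pre − t_post)
```

with potentiation when the pre spike precedes the post spike and depression
when it follows.

**Protocol.** Input is organized in 840 ms frames (10 frames = 1 epoch).
Five synchronized rows spike once per frame at a common phase; the other
15 rows are Bernoulli noise (`p_spike` per row per frame) at staggered
phases plus a uniform random offset (`Δ_offset`), with optional jitter
(`t_jitter`). At `p_spike = 1` every input averages 1.19 Hz.

## Worked example

Run the default coincidence-detection experiment (20 epochs, `p_spike = 1`,
no jitter or offset; 20 devices sampled with nominal 10 % threshold
variation, tuned to 16 µS):

```
$ memstdp simulate --seed 42 --out demo
post spikes: 200
final sync mean: 60.00 µS, noise mean: 16.17 µS
detection success: True
```

The neuron fired once per frame (200 post spikes in 200 frames). Each fire
happened during the synchronized pre plateau, so the five synchronized
synapses were repeatedly potentiated — their mean conductance rose from
16.2 µS to 60.0 µS (the top of the dynamic range) — while the 15 noise
synapses never saw a switching-capable overlap and stayed at 16.2 µS.
`detection success` reports that the synchronized group's final mean strictly
exceeds the noise group's, i.e. the neuron now responds selectively to the
synchronized pattern. `demo/trajectory.csv`, `demo/events.csv` and
`demo/summary.csv` hold the per-epoch conductances, the spike events, and the
group means.

The measured plasticity window of the nominal device:

```
$ memstdp stdp-window --points 41 --out window.csv
peak |ΔG/G0| = 95.8% at Δt = 5.0 ms
```

— a ≈+96 % conductance increase when the post spike follows the pre spike by
5 ms, ≈−50 % when it precedes it by 25–40 ms, and exactly zero once the
pulses no longer overlap (inside the 50–200 % band the pulse amplitudes were
chosen to produce).

Other entry points: `memstdp trials` (repeat with fresh noise),
`memstdp sweep` (per-column runs with freshly sampled devices),
`memstdp report` (summaries from a stored trajectory). The same operations
are available as library functions (`generate_session`, `run_experiment`,
`measure_stdp_window`, `summarize_groups`, ...).

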
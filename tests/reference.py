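"""Brute-force per-step reference simulator used as an oracle in tests.

Steps the public scalar operations (`step_neuron`, `step_device`,
`row_voltage`) one dt at a time with no vectorization or event skipping, and
replicates the engine's semantics: a post pulse launches at the step end where
the membrane crossed threshold, the neuron is frozen from the fire time for
max(refractory, post duration), every device sees row-minus-column voltage at
every step, and epoch-end readouts wait for an in-flight post pulse to finish.
"""

import numpy as np

from memstdp import (DeviceState, NeuronState, build_post_pulse,
                     build_pre_pulse, row_voltage, step_device, step_neuron,
                     synaptic_current)

EPS = 1e-9


def naive_run(session, devices, neuron, dt=0.5, initial=None):
    cfg = session.config
    pre = build_pre_pulse("main")
    post = build_post_pulse("main")
    post_dur = post.total_duration
    states = [DeviceState(g) for g in initial]
    nstate = NeuronState()
    post_t0 = None
    resume_t = -np.inf
    fires = []
    boundaries = [(e + 1) * cfg.frames_per_epoch * cfg.frame_duration
                  for e in range(cfg.n_epochs)]
    bi = 0
    end = boundaries[-1]
    last = max((o[-1] for o in session.onsets if o.size), default=-np.inf)
    end = max(end, last + pre.total_duration)
    n_steps = int(np.ceil(end / dt - EPS))
    traj = [np.array([s.g for s in states])]

    k = 0
    while k < n_steps:
        t = k * dt
        v_rows = np.array([row_voltage(pre, o, t) for o in session.onsets])
        active = post_t0 is not None and post_t0 - EPS <= t < post_t0 + post_dur - EPS
        v_col = post.value(t - post_t0) if active else 0.0
        states = [step_device(s, d, float(v - v_col), dt)
                  for s, d, v in zip(states, devices, v_rows)]
        if t < resume_t - EPS:
            nstate = NeuronState(neuron.u_reset, None)
        else:
            nstate, fired = step_neuron(
                nstate, neuron,
                synaptic_current([s.g for s in states], v_rows), dt)
            nstate = NeuronState(nstate.u, None)
            if fired:
                post_t0 = t + dt
                resume_t = post_t0 + max(neuron.refractory, post_dur)
                fires.append(post_t0)
                # a fire near the session end extends the loop so the post completes
                n_steps = max(n_steps, int(np.ceil((post_t0 + post_dur) / dt - EPS)))
        now = (k + 1) * dt
        while bi < len(boundaries) and boundaries[bi] <= now + EPS:
            b = boundaries[bi]
            spanning = (post_t0 is not None and post_t0 < b + EPS
                        and now < post_t0 + post_dur - EPS)
            if spanning:  # wait until the in-flight post pulse completes
                break
            traj.append(np.array([s.g for s in states]))
            bi += 1
        k += 1

    while bi < len(boundaries):  # boundaries reached only after the tail
        traj.append(np.array([s.g for s in states]))
        bi += 1
    return np.array(traj), np.array(fires)
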
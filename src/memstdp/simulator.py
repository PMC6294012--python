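"""Event loop coupling the spike protocol, waveforms, devices and neuron.

The simulation advances on a fixed grid of step ``dt`` (default 0.5 ms).  At
every step each row carries the voltage of its active pre pulse (or 0 V); the
neuron integrates the total synaptic current Σ GᵢVᵢ.  When the membrane crosses
threshold a post pulse is scheduled on the column at that instant, the
membrane resets and the neuron goes refractory; for the duration of the post
pulse every device is advanced under the difference voltage
``v_row - v_post``, which is the only time switching-capable voltages occur.
Threshold crossings during an ongoing post pulse are ignored (a single
waveform generator drives the column).  Conductances are recorded at the end
of every epoch, after any in-flight pulses have completed.

Implementation note: conductances can only change while a post pulse is
active, so between post pulses the membrane obeys a linear recurrence with
constant weights.  The engine therefore integrates the membrane in vectorized
blocks (scanning for the first threshold crossing in closed form) and drops to
per-step device updates only inside post-pulse windows.  This is numerically
identical to stepping :func:`memstdp.neuron.step_neuron` and
:func:`memstdp.memristor.step_device` one step at a time, which the test-suite
verifies against a brute-force reference loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .memristor import DeviceParams, DevicePopulation, tune_conductance
from .neuron import NeuronParams
from .protocol import ProtocolConfig, SpikeSession, generate_session
from .waveforms import build_post_pulse, build_pre_pulse, row_voltage

__all__ = [
    "SimConfig",
    "ExperimentResult",
    "run_experiment",
    "run_trials",
    "run_column_sweep",
]

_MAX_BLOCK = 2000  # membrane-recurrence block length (numerical headroom)


@dataclass(frozen=True)
class SimConfig:
    """Simulation controls: step (ms), recording, initial tuning target."""

    dt: float = 0.5
    record_membrane: bool = False
    initial_conductance_uS: float = 16.0
    tune_tolerance_uS: float = 0.2
    pulse_variant: str = "main"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.dt <= 1.0:
            raise ConfigurationError("dt must lie in (0, 1] ms")


@dataclass(frozen=True)
class ExperimentResult:
    """Per-epoch conductance trajectory plus events of one experiment run.

    ``g_trajectory`` has shape ``(n_epochs + 1, n_rows)``; row 0 is the tuned
    initial state.  ``post_spike_times`` are the absolute times (ms) at which
    the neuron fired and a post pulse was launched.  ``membrane_trace`` is an
    optional ``(t_ms, U_V)`` pair of arrays sampled at the simulation step
    (gaps correspond to refractory periods, where U is held at reset).
    """

    g_trajectory: np.ndarray
    post_spike_times: np.ndarray
    membrane_trace: Optional[tuple[np.ndarray, np.ndarray]]
    protocol: ProtocolConfig
    sim: SimConfig


def _membrane_block(u0: float, currents: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Membrane trajectory under the recurrence u_{m+1} = α·u_m + β·I_m.

    Returns u after 1..n steps given u0 and the n input-current samples.
    """
    k = np.arange(currents.size)
    decay = alpha ** k
    return (alpha * decay) * u0 + beta * decay * np.cumsum(currents / decay)


class _Engine:
    def __init__(self, session: SpikeSession, devices: Sequence[DeviceParams],
                 neuron: NeuronParams, sim: SimConfig, g0: np.ndarray):
        self.session = session
        self.neuron = neuron
        self.sim = sim
        self.dt = sim.dt
        self.pre = build_pre_pulse(sim.pulse_variant)
        self.post = build_post_pulse(sim.pulse_variant)
        self.pop = DevicePopulation(devices)
        self.g = g0.astype(float).copy()
        self.u = 0.0
        self.resume_step = 0  # first global step index at which integration may run
        self.fires: list[float] = []
        alpha = np.exp(-self.dt / neuron.tau)
        self.alpha = float(alpha)
        self.beta = float(neuron.current_gain * neuron.r_leak * 1e-3 * (1.0 - alpha))
        self.n_post = int(round(self.post.total_duration / self.dt))
        refr_steps = int(round(max(neuron.refractory, self.post.total_duration) / self.dt))
        self.refr_steps = max(refr_steps, self.n_post)
        self.v_col = self.post.value(np.arange(self.n_post) * self.dt)
        self.mem_t: list[np.ndarray] = []
        self.mem_u: list[np.ndarray] = []

    def _row_matrix(self, step0: int, n: int) -> tuple[np.ndarray, np.ndarray]:
        times = (step0 + np.arange(n)) * self.dt
        v = np.empty((self.session.n_rows, n))
        for r, onsets in enumerate(self.session.onsets):
            v[r] = row_voltage(self.pre, onsets, times)
        return times, v

    def _apply_post_window(self, fire_step: int) -> None:
        """Advance every device through one post pulse launched at fire_step."""
        _, v_rows = self._row_matrix(fire_step, self.n_post)
        g = self.g
        for m in range(self.n_post):
            g = self.pop.step(g, v_rows[:, m] - self.v_col[m], self.dt)
        self.g = g

    def advance(self, start_step: int, end_step: int) -> None:
        """Integrate the membrane over [start_step, end_step), firing as needed."""
        i = max(start_step, self.resume_step)
        while i < end_step:
            n = min(end_step - i, _MAX_BLOCK)
            times, v_rows = self._row_matrix(i, n)
            currents = self.g @ v_rows
            u_traj = _membrane_block(self.u, currents, self.alpha, self.beta)
            above = u_traj >= self.neuron.u_threshold
            if not above.any():
                if self.sim.record_membrane:
                    self.mem_t.append(times + self.dt)
                    self.mem_u.append(u_traj)
                self.u = float(u_traj[-1])
                i += n
                continue
            m = int(np.argmax(above))
            if self.sim.record_membrane:
                self.mem_t.append(times[: m + 1] + self.dt)
                self.mem_u.append(u_traj[: m + 1])
            fire_step = i + m + 1  # crossing detected at the end of step m
            self.fires.append(fire_step * self.dt)
            self.u = self.neuron.u_reset
            self._apply_post_window(fire_step)
            self.resume_step = fire_step + self.refr_steps
            i = max(self.resume_step, i + m + 1)

    def tail_end_step(self, nominal_end_step: int) -> int:
        """Step until which simulation must continue so all pulses complete."""
        last = max((o[-1] for o in self.session.onsets if o.size), default=-np.inf)
        if last == -np.inf:
            return max(nominal_end_step, self.resume_step)
        pre_end = int(np.ceil((last + self.pre.total_duration) / self.dt))
        return max(nominal_end_step, pre_end, self.resume_step)


def run_experiment(session: SpikeSession, devices: Sequence[DeviceParams],
                   neuron: NeuronParams = NeuronParams(), sim: SimConfig = SimConfig(),
                   initial: Optional[np.ndarray] = None) -> ExperimentResult:
    """Run one coincidence-detection experiment.

    ``devices`` supplies one parameter set per crossbar row.  ``initial`` gives
    the starting conductances; when omitted every device is first tuned to
    ``sim.initial_conductance_uS`` with the write-verify loop.  Conductances
    are recorded at epoch boundaries (after in-flight pulses have ended); the
    returned trajectory has ``n_epochs + 1`` rows, the first being the initial
    state.
    """
    cfg = session.config
    if len(devices) != session.n_rows:
        raise ConfigurationError(
            f"{len(devices)} devices for {session.n_rows} rows")
    steps_per_frame = cfg.frame_duration / sim.dt
    if abs(steps_per_frame - round(steps_per_frame)) > 1e-9:
        raise ConfigurationError("dt must divide the frame duration")
    steps_per_frame = int(round(steps_per_frame))
    if initial is None:
        g0 = np.array([
            tune_conductance(d, sim.initial_conductance_uS, tol=sim.tune_tolerance_uS).g
            for d in devices])
    else:
        g0 = np.asarray(initial, dtype=float)
        if g0.shape != (session.n_rows,):
            raise ConfigurationError("initial conductances must match the row count")

    eng = _Engine(session, devices, neuron, sim, g0)
    total_frames = cfg.n_epochs * cfg.frames_per_epoch
    traj = np.empty((cfg.n_epochs + 1, session.n_rows))
    traj[0] = eng.g
    for f in range(total_frames):
        start, end = f * steps_per_frame, (f + 1) * steps_per_frame
        if f == total_frames - 1:
            end = eng.tail_end_step(end)
        eng.advance(start, end)
        if (f + 1) % cfg.frames_per_epoch == 0:
            traj[(f + 1) // cfg.frames_per_epoch] = eng.g
    trace = None
    if sim.record_membrane:
        trace = (np.concatenate(eng.mem_t) if eng.mem_t else np.empty(0),
                 np.concatenate(eng.mem_u) if eng.mem_u else np.empty(0))
    return ExperimentResult(traj, np.asarray(eng.fires), trace, cfg, sim)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def run_trials(cfg: ProtocolConfig, devices: Sequence[DeviceParams],
               neuron: NeuronParams = NeuronParams(), sim: SimConfig = SimConfig(),
               n_trials: int = 15, seed: int = 0,
               device_factory: Optional[Callable[[int], Sequence[DeviceParams]]] = None,
               session_factory: Optional[Callable[[ProtocolConfig], SpikeSession]] = None,
               ) -> list[ExperimentResult]:
    """Repeat the experiment with fresh noise; devices re-tuned before each trial.

    Sessions use per-trial seeds derived from ``seed`` (noise spikes are unique
    in every trial).  The same device population is reused unless a
    ``device_factory(trial_seed)`` is supplied to resample it per trial.
    ``session_factory`` may override plain :func:`generate_session` (e.g. for
    two-pattern sessions).
    """
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    make_session = session_factory or generate_session
    results = []
    for trial_seed in _child_seeds(seed, n_trials):
        session = make_session(replace(cfg, seed=int(trial_seed)))
        devs = device_factory(int(trial_seed)) if device_factory else devices
        results.append(run_experiment(session, devs, neuron, sim))
    return results


def run_column_sweep(nominal: DeviceParams, variation, cfg: ProtocolConfig,
                     neuron: NeuronParams = NeuronParams(), sim: SimConfig = SimConfig(),
                     n_columns: int = 20, epochs: int = 20, seed: int = 0) -> np.ndarray:
    """Relative conductance change per (column, row) after ``epochs`` epochs.

    Each column is simulated independently (only one column is ever connected
    to the neuron; the rest are grounded) with its own freshly sampled device
    population and its own noise realization.  Returns an
    ``(n_columns, n_rows)`` array of ``(G_end - G_start) / G_start``.
    """
    from .memristor import sample_devices  # local import to avoid cycle noise

    col_seeds = _child_seeds(seed, 2 * n_columns).reshape(n_columns, 2)
    cfg = replace(cfg, n_epochs=epochs)
    out = np.empty((n_columns, cfg.n_rows))
    for c in range(n_columns):
        devs = sample_devices(nominal, replace(variation, seed=int(col_seeds[c, 0])), cfg.n_rows)
        session = generate_session(replace(cfg, seed=int(col_seeds[c, 1])))
        res = run_experiment(session, devs, neuron, sim)
        out[c] = (res.g_trajectory[-1] - res.g_trajectory[0]) / res.g_trajectory[0]
    return out
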
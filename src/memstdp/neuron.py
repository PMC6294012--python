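"""Leaky integrate-and-fire neuron.

Membrane dynamics: ``C dU/dt = I_in(t) - U/R_L`` with the resting potential as
the reference for ``U``.  ``I_in`` is the total synaptic current, the dot
product of row voltages and synaptic conductances (µS × V = µA); the
characteristic time is ``τ = R_L · C`` (kΩ · µF = ms), 90 ms at the default
900 kΩ / 0.1 µF.  Integration uses exponential Euler, which is exact for
piecewise-constant input current::

    U ← U · e^(-dt/τ) + gain · I_in · R_L · (1 - e^(-dt/τ))

On reaching ``u_threshold`` the neuron fires (triggering the post-synaptic
spike in the full simulator), resets to ``u_reset`` and holds there for the
refractory period, during which no integration occurs — mirroring the analogue
neuron being disconnected from the crossbar while the post waveform plays out.

``current_gain`` and ``u_threshold`` absorb the analogue front-end (op-amp
stages and variable resistors) into two numbers; the default threshold is
calibrated so that four or more coincident spikes through 16 µS synapses fire
the neuron while two or fewer do not.  It sits near the top of that window
(four simultaneous 16 µS inputs peak at ≈3.5 V, three at ≈2.6 V) so that
sub-coincidence activity — three inputs at the operating point, or a single
fully potentiated synapse — cannot fire a detector meant to respond to
synchrony.  The negative tail of a pre pulse
contributes negative current exactly like any other sample; no rectification
is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError

__all__ = ["NeuronParams", "NeuronState", "step_neuron", "synaptic_current"]


@dataclass(frozen=True)
class NeuronParams:
    """LIF parameters: capacitance µF, leak kΩ, potentials V, refractory ms."""

    c_mem: float = 0.1
    r_leak: float = 900.0
    u_threshold: float = 3.0
    u_reset: float = 0.0
    refractory: float = 56.0  # matches the main post-pulse duration
    current_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.c_mem <= 0 or self.r_leak <= 0:
            raise ConfigurationError("c_mem and r_leak must be positive")
        if self.u_threshold <= self.u_reset:
            raise ConfigurationError("u_threshold must exceed u_reset")
        if self.refractory < 0:
            raise ConfigurationError("refractory must be >= 0")

    @property
    def tau(self) -> float:
        """Membrane time constant R_L·C in ms."""
        return self.r_leak * self.c_mem


@dataclass(frozen=True)
class NeuronState:
    """Membrane potential (V) and, if refractory, time since the last fire (ms)."""

    u: float = 0.0
    time_since_fire: Optional[float] = None


def step_neuron(state: NeuronState, params: NeuronParams, i_in: float,
                dt: float) -> tuple[NeuronState, bool]:
    """One exponential-Euler step of ``dt`` ms with input current ``i_in`` µA.

    Returns the new state and a flag that is True when the membrane crossed
    threshold during this step (the state is then already reset and
    refractory).  While refractory the membrane is held at ``u_reset``.
    """
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if state.time_since_fire is not None:
        tsf = state.time_since_fire + dt
        if tsf < params.refractory:
            return NeuronState(params.u_reset, tsf), False
        state = NeuronState(params.u_reset, None)
    alpha = math.exp(-dt / params.tau)
    # µA × kΩ = mV, hence the 1e-3 to express U in volts.
    u = alpha * state.u + params.current_gain * i_in * params.r_leak * 1e-3 * (1.0 - alpha)
    if u >= params.u_threshold:
        return NeuronState(params.u_reset, 0.0), True
    return NeuronState(u, None), False


def synaptic_current(conductances, row_voltages) -> float:
    """Total synaptic current Σᵢ Gᵢ·Vᵢ in µA (conductances µS, voltages V)."""
    g = np.asarray(conductances, dtype=float)
    v = np.asarray(row_voltages, dtype=float)
    if g.shape != v.shape:
        raise ValueError(f"length mismatch: {g.shape} vs {v.shape}")
    return float(g @ v)
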
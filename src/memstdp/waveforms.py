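"""Piecewise-linear spike waveforms and voltages across a crossbar device.

The network uses rectangular-ish pre- and post-synaptic voltage spikes built
from linear ramps and plateaus.  A synapse (memristor) sits between a row
(driven by the pre-synaptic spike) and a column (driven by the post-synaptic
spike while the output neuron is firing, otherwise held at virtual ground), so
the voltage that can switch the device is the instantaneous difference
``v_row - v_col``.  Either pulse alone stays below the switching thresholds;
only overlapping pre/post pulses produce a switching-capable voltage
(half-select safety), which is what realizes spike-timing-dependent plasticity
in the hardware.

Two protocol variants are provided:

``main``
    the coincidence-detection protocol: 38 ms pre spike
    (ramp to +0.45 V, 0.63 V plateau, -0.4 V tail) and a post spike whose
    printed segments sum to 56 ms (ramp from -0.15 V to +0.65 V, +0.6 V
    plateau, -1.15 V plateau, ramp back), with a -0.15 V baseline on the
    column while the post spike is scheduled.

``characterization``
    the variant used for device STDP-window characterization: 42 ms pre and
    57 ms post spikes, both returning to a 0 V baseline.

Evaluation is right-continuous at segment boundaries: a printed step such as
the pre spike's +0.45 V ramp end followed by the 0.63 V plateau takes the
later segment's value at the boundary instant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, ProtocolError

__all__ = [
    "PulseSegment",
    "PulseShape",
    "build_pre_pulse",
    "build_post_pulse",
    "pulse_value",
    "row_voltage",
    "device_voltage",
]


@dataclass(frozen=True)
class PulseSegment:
    """One linear piece of a pulse: ``duration`` ms from ``v_start`` to ``v_end`` volts."""

    duration: float
    v_start: float
    v_end: float

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ConfigurationError(f"segment duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class PulseShape:
    """An ordered sequence of :class:`PulseSegment` plus a baseline voltage.

    ``value(t)`` evaluates the waveform at time ``t`` (ms) since pulse onset;
    outside ``[0, total_duration)`` the baseline is returned.  Voltage
    discontinuities between consecutive segments are permitted and resolved
    right-continuously.
    """

    segments: tuple[PulseSegment, ...]
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ConfigurationError("a pulse shape needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    @cached_property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    @cached_property
    def _bounds(self) -> np.ndarray:
        # cumulative segment start times [0, d1, d1+d2, ...]
        return np.concatenate([[0.0], np.cumsum([s.duration for s in self.segments])])

    @cached_property
    def _arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        dur = np.array([s.duration for s in self.segments])
        v0 = np.array([s.v_start for s in self.segments])
        v1 = np.array([s.v_end for s in self.segments])
        return dur, v0, v1

    def value(self, t):
        """Voltage at time(s) ``t`` ms since pulse onset (scalar or ndarray)."""
        t_arr = np.asarray(t, dtype=float)
        scalar = t_arr.ndim == 0
        t_arr = np.atleast_1d(t_arr)
        out = np.full(t_arr.shape, self.baseline, dtype=float)
        inside = (t_arr >= 0.0) & (t_arr < self.total_duration)
        if inside.any():
            dur, v0, v1 = self._arrays
            idx = np.searchsorted(self._bounds, t_arr[inside], side="right") - 1
            idx = np.clip(idx, 0, len(self.segments) - 1)
            frac = (t_arr[inside] - self._bounds[idx]) / dur[idx]
            out[inside] = v0[idx] + frac * (v1[idx] - v0[idx])
        return float(out[0]) if scalar else out

    # -- config (de)serialization: ordered (duration, v_start, v_end) triplets --

    def to_triplets(self) -> list[list[float]]:
        return [[s.duration, s.v_start, s.v_end] for s in self.segments]

    @classmethod
    def from_triplets(cls, triplets: Iterable[Sequence[float]], baseline: float = 0.0) -> "PulseShape":
        return cls(tuple(PulseSegment(*map(float, t)) for t in triplets), baseline=float(baseline))


# Printed protocol segment lists, in ms and V.
_PRE_SEGMENTS = {
    "main": [(5, 0.0, 0.45), (7, 0.63, 0.63), (1, 0.63, -0.4), (20, -0.4, -0.4), (5, -0.4, 0.0)],
    "characterization": [(5, 0.0, 0.63), (10, 0.63, 0.63), (2, 0.63, -0.54), (20, -0.54, -0.54), (5, -0.54, 0.0)],
}
_POST_SEGMENTS = {
    "main": [(5, -0.15, 0.65), (23, 0.6, 0.6), (1, 0.6, -1.15), (22, -1.15, -1.15), (5, -1.15, -0.15)],
    "characterization": [(5, 0.0, 0.6), (23, 0.6, 0.6), (2, 0.6, -0.5), (22, -0.5, -0.5), (5, -0.5, 0.0)],
}
_POST_BASELINE = {"main": -0.15, "characterization": 0.0}


def build_pre_pulse(variant: str = "main") -> PulseShape:
    """Pre-synaptic (row) spike for the named protocol variant; 0 V baseline."""
    try:
        segs = _PRE_SEGMENTS[variant]
    except KeyError:
        raise ConfigurationError(f"unknown pre-pulse variant {variant!r}") from None
    return PulseShape.from_triplets(segs, baseline=0.0)


def build_post_pulse(variant: str = "main") -> PulseShape:
    """Post-synaptic (column) spike for the named protocol variant.

    The ``main`` variant holds the column at -0.15 V while the post spike is
    scheduled (a convenience of the analogue neuron, not essential); outside a
    scheduled post spike the column is at virtual ground, which the simulator
    handles — the baseline here applies only within scheduling logic.
    """
    try:
        segs = _POST_SEGMENTS[variant]
    except KeyError:
        raise ConfigurationError(f"unknown post-pulse variant {variant!r}") from None
    return PulseShape.from_triplets(segs, baseline=_POST_BASELINE[variant])


def pulse_value(shape: PulseShape, t):
    """Voltage of ``shape`` at time(s) ``t`` ms since onset (total function of t)."""
    return shape.value(t)


def row_voltage(pre_shape: PulseShape, onsets, t):
    """Row voltage at time(s) ``t`` given sorted pulse ``onsets`` (absolute ms).

    At most one pulse instance may be active at a time; the protocol guarantees
    per-row onset gaps of at least the pulse duration, and a violation raises
    :class:`ProtocolError`.  With no active instance the row is at 0 V.
    """
    onsets = np.asarray(onsets, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if onsets.size == 0:
        out = np.zeros(t_arr.shape)
        return float(out[0]) if scalar else out
    if np.any(np.diff(onsets) < pre_shape.total_duration - 1e-9):
        raise ProtocolError("overlapping pulse instances on one row")
    k = np.searchsorted(onsets, t_arr, side="right") - 1
    elapsed = t_arr - onsets[np.clip(k, 0, None)]
    vals = pre_shape.value(elapsed)
    out = np.where(k >= 0, vals, 0.0)
    return float(out[0]) if scalar else out


def device_voltage(v_row, v_col):
    """Instantaneous voltage across a device: row minus column potential."""
    return v_row - v_col
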
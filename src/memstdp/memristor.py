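"""Voltage-threshold memristor model: switching dynamics, variation, tuning, STDP window.

A device holds a conductance ``g`` inside its dynamic range ``[g_min, g_max]``
(µS).  Switching is polarity- and threshold-gated with exponential voltage
acceleration and linear saturation toward the range edge:

* set (potentiation), for device voltage ``v <= -v_set``::

      dG/dt = +k_set * exp((|v| - v_set) / v0_set) * (g_max - G) / (g_max - g_min)

* reset (depression), for ``v >= +v_reset``::

      dG/dt = -k_reset * exp((v - v_reset) / v0_reset) * (G - g_min) / (g_max - g_min)

* otherwise ``dG/dt = 0``.

``v_set`` sits above the largest lone pre-pulse amplitude (0.63 V) and
``v_reset`` above the largest lone post-pulse amplitude (1.15 V), so isolated
pulses never disturb a device (half-select safety); only overlapping pre/post
pulses — the -1.0 V pre-tail-over-post-plateau combination (set) and the
+1.78 V pre-plateau-over-negative-post-plateau combination (reset) — switch it.
Reset uses the larger-magnitude combination, mirroring reset thresholds being
larger in magnitude than set thresholds in the physical devices.

For a voltage held constant over a step the rate law is linear in ``G``, so
:func:`step_device` advances with the exact per-step exponential solution; a
brute-force fine-grid Euler integrator serves as an independent oracle in the
test-suite.

Rate constants ``k_set``/``k_reset`` and slopes ``v0_*`` are calibration
parameters (chosen so the nominal device's STDP window peaks near +100 %/-50 %
relative change at the 16 µS operating point); the thresholds and dynamic
range defaults sit mid-way inside the windows the half-select constraints
allow.  Device-to-device variation is modelled as independent Gaussian
relative perturbations of the parameters, with thresholds clipped to preserve
half-select safety.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, TuningError
from .waveforms import PulseShape, build_post_pulse, build_pre_pulse

__all__ = [
    "DeviceParams",
    "DeviceState",
    "VariationModel",
    "DevicePopulation",
    "step_device",
    "sample_devices",
    "tune_conductance",
    "measure_stdp_window",
]

# Half-select safety bounds: lone pre pulses reach 0.63 V, lone post pulses
# 1.15 V; overlapping pulses reach 1.0 V (set polarity) and 1.78 V (reset).
_VSET_CLIP = (0.64, 1.0)
_VRESET_CLIP = (1.16, 1.78)


@dataclass(frozen=True)
class DeviceParams:
    """Nominal memristor parameters (conductances µS, voltages V, rates µS/ms)."""

    g_min: float = 2.0
    g_max: float = 60.0
    v_set: float = 0.8
    v_reset: float = 1.4
    k_set: float = 0.17
    k_reset: float = 0.15
    v0_set: float = 0.1
    v0_reset: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.g_min < self.g_max:
            raise ConfigurationError("need 0 < g_min < g_max")
        if self.v_set <= 0 or self.v_reset <= 0 or self.v0_set <= 0 or self.v0_reset <= 0:
            raise ConfigurationError("thresholds and slope voltages must be positive")
        if self.k_set < 0 or self.k_reset < 0:
            raise ConfigurationError("rate prefactors must be non-negative")


@dataclass(frozen=True)
class DeviceState:
    """Current conductance of one device, µS."""

    g: float


@dataclass(frozen=True)
class VariationModel:
    """Relative (fractional) standard deviations for device-to-device sampling."""

    sigma_v_set: float = 0.10
    sigma_v_reset: float = 0.10
    sigma_k_set: float = 0.10
    sigma_k_reset: float = 0.10
    sigma_g_min: float = 0.05
    sigma_g_max: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name.startswith("sigma") and getattr(self, f.name) < 0:
                raise ConfigurationError("variation sigmas must be >= 0")


def step_device(state: DeviceState, params: DeviceParams, v_dev: float, dt: float) -> DeviceState:
    """Advance one device by ``dt`` ms under constant voltage ``v_dev``.

    Uses the exact exponential solution of the (linear-in-G) rate law over the
    step; the result is clipped to the dynamic range.
    """
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    g = state.g
    span = params.g_max - params.g_min
    if v_dev <= -params.v_set:
        a = params.k_set * math.exp((-v_dev - params.v_set) / params.v0_set) / span
        g = params.g_max - (params.g_max - g) * math.exp(-a * dt)
    elif v_dev >= params.v_reset:
        b = params.k_reset * math.exp((v_dev - params.v_reset) / params.v0_reset) / span
        g = params.g_min + (g - params.g_min) * math.exp(-b * dt)
    return DeviceState(min(max(g, params.g_min), params.g_max))


class DevicePopulation:
    """Struct-of-arrays view of a device list with a vectorized step (simulator hot path)."""

    def __init__(self, devices: Sequence[DeviceParams]):
        self.devices = tuple(devices)
        self.g_min = np.array([d.g_min for d in devices])
        self.g_max = np.array([d.g_max for d in devices])
        self.v_set = np.array([d.v_set for d in devices])
        self.v_reset = np.array([d.v_reset for d in devices])
        self.k_set = np.array([d.k_set for d in devices])
        self.k_reset = np.array([d.k_reset for d in devices])
        self.v0_set = np.array([d.v0_set for d in devices])
        self.v0_reset = np.array([d.v0_reset for d in devices])
        self._span = self.g_max - self.g_min

    def __len__(self) -> int:
        return len(self.devices)

    def step(self, g: np.ndarray, v_dev: np.ndarray, dt: float) -> np.ndarray:
        """Exact-exponential update of all conductances; returns a new array."""
        g = g.copy()
        m = v_dev <= -self.v_set
        if m.any():
            a = self.k_set[m] * np.exp((-v_dev[m] - self.v_set[m]) / self.v0_set[m]) / self._span[m]
            g[m] = self.g_max[m] - (self.g_max[m] - g[m]) * np.exp(-a * dt)
        m = v_dev >= self.v_reset
        if m.any():
            b = self.k_reset[m] * np.exp((v_dev[m] - self.v_reset[m]) / self.v0_reset[m]) / self._span[m]
            g[m] = self.g_min[m] + (g[m] - self.g_min[m]) * np.exp(-b * dt)
        return np.clip(g, self.g_min, self.g_max)


def sample_devices(nominal: DeviceParams, var: VariationModel, n: int) -> list[DeviceParams]:
    """Draw ``n`` parameter sets with Gaussian relative perturbations.

    Thresholds are clipped to keep half-select safety (lone pulses never
    switch) while overlapped pulses remain switching-capable; deterministic
    given ``var.seed``.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(var.seed)
    out = []
    for _ in range(n):
        v_set = nominal.v_set * (1.0 + rng.normal(0.0, var.sigma_v_set))
        v_reset = nominal.v_reset * (1.0 + rng.normal(0.0, var.sigma_v_reset))
        k_set = nominal.k_set * (1.0 + rng.normal(0.0, var.sigma_k_set))
        k_reset = nominal.k_reset * (1.0 + rng.normal(0.0, var.sigma_k_reset))
        g_min = nominal.g_min * (1.0 + rng.normal(0.0, var.sigma_g_min))
        g_max = nominal.g_max * (1.0 + rng.normal(0.0, var.sigma_g_max))
        g_min = max(g_min, 0.2)
        g_max = max(g_max, g_min + 5.0)
        out.append(DeviceParams(
            g_min=g_min,
            g_max=g_max,
            v_set=float(np.clip(v_set, *_VSET_CLIP)),
            v_reset=float(np.clip(v_reset, *_VRESET_CLIP)),
            k_set=max(k_set, 1e-4),
            k_reset=max(k_reset, 1e-4),
            v0_set=nominal.v0_set,
            v0_reset=nominal.v0_reset,
        ))
    return out


def tune_conductance(params: DeviceParams, target: float, tol: float = 0.8,
                     state: Optional[DeviceState] = None, max_iter: int = 1000,
                     pulse_ms: float = 1.0, amp_start: float = 0.05,
                     amp_step: float = 0.02, amp_max: float = 0.5) -> DeviceState:
    """Write-verify feedback loop driving a device to ``target`` µS within ``tol``.

    Applies fixed-width set/reset pulses whose over-threshold amplitude grows
    while the error keeps the same sign and restarts small on a sign flip,
    re-reading the (noiseless) conductance after each write.  Starts from the
    middle of the dynamic range when no ``state`` is given.  A device already
    within tolerance receives zero write pulses.
    """
    if not tol > 0:
        raise ConfigurationError("tol must be > 0")
    if not params.g_min < target < params.g_max:
        raise TuningError(f"target {target} µS outside device range "
                          f"({params.g_min}, {params.g_max})")
    if state is None:
        state = DeviceState(0.5 * (params.g_min + params.g_max))
    amp = amp_start
    last_direction = 0
    for _ in range(max_iter):
        err = state.g - target
        if abs(err) <= tol:
            return state
        direction = 1 if err < 0 else -1  # +1: need set, -1: need reset
        if direction != last_direction:
            amp = amp_start
        v = -(params.v_set + amp) if direction > 0 else (params.v_reset + amp)
        state = step_device(state, params, v, pulse_ms)
        amp = min(amp + amp_step, amp_max)
        last_direction = direction
    raise TuningError(f"tuning to {target} µS did not converge in {max_iter} pulses")


def _simulate_pulse_pair(params: DeviceParams, g0: float, pre: PulseShape,
                         post: PulseShape, lag: float, sim_dt: float) -> float:
    """Final conductance after one pre pulse at t=0 and one post pulse at t=lag."""
    t0 = min(0.0, lag)
    t1 = max(pre.total_duration, lag + post.total_duration)
    times = np.arange(t0, t1 + sim_dt, sim_dt)
    v_pre = pre.value(times)
    in_post = (times >= lag) & (times < lag + post.total_duration)
    v_col = np.where(in_post, post.value(times - lag), 0.0)
    v = v_pre - v_col
    state = DeviceState(g0)
    vs, vr = -params.v_set, params.v_reset
    for vv in v:
        if vv <= vs or vv >= vr:
            state = step_device(state, params, float(vv), sim_dt)
    return state.g


def measure_stdp_window(params: DeviceParams, dt_grid: Sequence[float],
                        pulse_variant: str = "main", baseline_uS: float = 16.0,
                        tune_tol: float = 0.2, sim_dt: float = 0.1) -> np.ndarray:
    """Measured STDP window: relative conductance change vs pre/post lag.

    For each lag ``Δt = t_post_onset - t_pre_onset`` in ``dt_grid`` the device
    is first tuned to ``baseline_uS``, then a single pre and a single post
    pulse are applied at that lag and the device is integrated under their
    difference voltage.  Returns an ``(n, 2)`` array of ``(Δt ms, ΔG/G0 %)``.
    """
    pre = build_pre_pulse(pulse_variant)
    post = build_post_pulse(pulse_variant)
    out = np.empty((len(dt_grid), 2))
    for i, lag in enumerate(dt_grid):
        state = tune_conductance(params, baseline_uS, tol=tune_tol)
        g0 = state.g
        g1 = _simulate_pulse_pair(params, g0, pre, post, float(lag), sim_dt)
        out[i] = (lag, (g1 - g0) / g0 * 100.0)
    return out
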
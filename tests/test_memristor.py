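"""Device model: switching law vs fine-grid oracle, variation, tuning, STDP window."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memstdp import (DeviceParams, DeviceState, TuningError, VariationModel,
                     measure_stdp_window, sample_devices, step_device,
                     tune_conductance)


def euler_reference(params: DeviceParams, g0: float, v: float, duration: float,
                    dt: float = 0.01) -> float:
    """Independent 10 µs explicit-Euler integrator of the switching rate law."""
    g = g0
    span = params.g_max - params.g_min
    steps = int(round(duration / dt))
    for _ in range(steps):
        if v <= -params.v_set:
            g += dt * params.k_set * np.exp((-v - params.v_set) / params.v0_set) * (params.g_max - g) / span
        elif v >= params.v_reset:
            g -= dt * params.k_reset * np.exp((v - params.v_reset) / params.v0_reset) * (g - params.g_min) / span
        g = min(max(g, params.g_min), params.g_max)
    return g


def test_subthreshold_voltage_leaves_device_untouched(nominal_device):
    s = DeviceState(16.0)
    for v in (-0.79, -0.63, 0.0, 0.63, 1.15, 1.39):
        assert step_device(s, nominal_device, v, 50.0).g == 16.0


def test_saturation_at_range_edges(nominal_device):
    top = DeviceState(nominal_device.g_max)
    assert step_device(top, nominal_device, -1.0, 100.0).g == nominal_device.g_max
    bottom = DeviceState(nominal_device.g_min)
    assert step_device(bottom, nominal_device, 1.78, 100.0).g == nominal_device.g_min


@pytest.mark.parametrize("v,duration", [(-1.0, 20.0), (1.78, 7.0), (-0.9, 40.0), (1.5, 30.0)])
def test_step_agrees_with_fine_grid_oracle(nominal_device, v, duration):
    """Main stepper vs 10 µs explicit-Euler reference: within 1 %."""
    got = step_device(DeviceState(16.0), nominal_device, v, duration).g
    ref = euler_reference(nominal_device, 16.0, v, duration)
    assert got == pytest.approx(ref, rel=0.01)


def test_step_dt_refinement_converges(nominal_device):
    """Integrating in one step vs ten sub-steps agrees within 1 % (constant v)."""
    for v in (-1.0, 1.78):
        coarse = step_device(DeviceState(16.0), nominal_device, v, 5.0).g
        s = DeviceState(16.0)
        for _ in range(10):
            s = step_device(s, nominal_device, v, 0.5)
        assert coarse == pytest.approx(s.g, rel=0.01)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=-2.0, max_value=2.0, allow_nan=False), min_size=1, max_size=40),
       st.floats(min_value=2.0, max_value=60.0))
def test_conductance_never_leaves_dynamic_range(voltages, g0):
    params = DeviceParams()
    s = DeviceState(g0)
    for v in voltages:
        s = step_device(s, params, v, 1.7)
        assert params.g_min <= s.g <= params.g_max


def test_half_select_safety_pre_only_and_post_only_trains(nominal_device):
    """Lone pre pulses (<=0.63 V) or lone post pulses (<=1.15 V) never switch."""
    from memstdp import build_post_pulse, build_pre_pulse

    # a lone pre puts v_pre across the device; a lone post, driven on the
    # column, appears inverted: -v_post
    for shape, sign in ((build_pre_pulse("main"), 1.0),
                        (build_post_pulse("main"), -1.0)):
        s = DeviceState(16.0)
        ts = np.arange(0.0, shape.total_duration, 0.1)
        for rep in range(5):
            for t in ts:
                s = step_device(s, nominal_device, sign * shape.value(t), 0.1)
        assert s.g == 16.0


def test_sample_devices_zero_sigma_copies(nominal_device):
    devs = sample_devices(nominal_device, VariationModel(0, 0, 0, 0, 0, 0, seed=3), 5)
    assert all(d == nominal_device for d in devs)


def test_sample_devices_deterministic_and_clt(nominal_device):
    var = VariationModel(sigma_v_set=0.10, seed=42)
    a = sample_devices(nominal_device, var, 20)
    b = sample_devices(nominal_device, var, 20)
    assert a == b
    vsets = np.array([d.v_set for d in a])
    se = 0.10 * nominal_device.v_set / np.sqrt(20)
    assert abs(vsets.mean() - nominal_device.v_set) <= 3 * se
    # half-select safety survives sampling
    assert all(d.v_set > 0.63 and d.v_reset > 1.15 for d in a)


def test_tuning_within_tolerance_needs_no_writes(nominal_device):
    s0 = DeviceState(16.5)
    assert tune_conductance(nominal_device, 16.0, tol=0.8, state=s0) is s0


def test_tuning_converges_from_range_bottom(nominal_device):
    s = tune_conductance(nominal_device, 16.0, tol=0.8, state=DeviceState(nominal_device.g_min))
    assert abs(s.g - 16.0) <= 0.8


def test_tuning_unreachable_target_raises(nominal_device):
    with pytest.raises(TuningError):
        tune_conductance(nominal_device, 100.0)


def test_population_tunes_to_16uS(nominal_device):
    devs = sample_devices(nominal_device, VariationModel(seed=7), 20)
    rng = np.random.default_rng(7)
    tuned = [tune_conductance(d, 16.0, tol=0.8,
                              state=DeviceState(rng.uniform(d.g_min + 0.5, d.g_max - 0.5))).g
             for d in devs]
    assert all(abs(g - 16.0) <= 0.8 for g in tuned)
    assert np.mean(tuned) == pytest.approx(16.0, abs=0.8)


def test_stdp_window_shape(nominal_device):
    grid = np.arange(-100.0, 101.0, 5.0)
    w = measure_stdp_window(nominal_device, grid)
    lags, dg = w[:, 0], w[:, 1]
    # zero outside any pre/post overlap
    assert np.all(dg[np.abs(lags) >= 60.0] == 0.0)
    # potentiation branch: post shortly after pre
    assert np.all(dg[(lags >= 0) & (lags <= 10)] > 0)
    # depression branch: pre well after post
    assert np.all(dg[(lags >= -40) & (lags <= -25)] < 0)
    # calibrated peak magnitude inside the 50-200 % band
    assert 50.0 <= np.abs(dg).max() <= 200.0


def test_larger_thresholds_give_smaller_updates(nominal_device):
    """Devices with larger switching thresholds change less at a fixed lag."""
    import dataclasses

    lag = [6.0, -30.0]
    small = measure_stdp_window(nominal_device, lag)
    big = measure_stdp_window(
        dataclasses.replace(nominal_device, v_set=0.95, v_reset=1.6), lag)
    assert abs(big[0, 1]) < abs(small[0, 1])
    assert abs(big[1, 1]) < abs(small[1, 1])
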
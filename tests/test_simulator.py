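"""Event loop: oracle cross-check, determinism, convergence, learning properties."""

import dataclasses

import numpy as np
import pytest

from memstdp import (ConfigurationError, DeviceParams, NeuronParams,
                     ProtocolConfig, SimConfig, VariationModel,
                     generate_session, run_column_sweep, run_experiment,
                     run_trials, sample_devices, summarize_groups)
from conftest import sync_noise_groups
from reference import naive_run


def test_engine_matches_per_step_reference(tiny_protocol, neuron):
    """The vectorized engine reproduces a brute-force step-by-step loop built
    from the public scalar operations: same fire times, same trajectory."""
    session = generate_session(tiny_protocol)
    devices = sample_devices(DeviceParams(), VariationModel(seed=4), 20)
    initial = np.full(20, 16.0)
    res = run_experiment(session, devices, neuron, SimConfig(dt=0.5), initial=initial)
    ref_traj, ref_fires = naive_run(session, devices, neuron, dt=0.5, initial=initial)
    assert len(res.post_spike_times) == len(ref_fires) > 0
    np.testing.assert_allclose(res.post_spike_times, ref_fires, atol=1e-9)
    np.testing.assert_allclose(res.g_trajectory, ref_traj, atol=1e-8)


def test_empty_session_changes_nothing(neuron):
    cfg = ProtocolConfig(n_epochs=2, p_spike=0.0, synchronized_rows=())
    session = generate_session(cfg)
    res = run_experiment(session, [DeviceParams()] * 20, neuron,
                         initial=np.full(20, 16.0))
    assert len(res.post_spike_times) == 0
    assert np.all(res.g_trajectory == 16.0)
    assert res.g_trajectory.shape == (3, 20)


def test_sync_only_learning_potentiates_sync_rows(neuron):
    """5 synchronized rows, no noise: sync conductances rise epoch over epoch
    (until saturation), all other rows stay exactly flat."""
    cfg = ProtocolConfig(n_epochs=2, p_spike=0.0, seed=0)
    session = generate_session(cfg)
    res = run_experiment(session, [DeviceParams()] * 20, neuron,
                         initial=np.full(20, 16.0))
    traj = res.g_trajectory
    sync = list(cfg.synchronized_rows)
    noise = [r for r in range(20) if r not in sync]
    assert np.all(traj[1, sync] > traj[0, sync])
    assert np.all(traj[2, sync] >= traj[1, sync])
    assert np.all(traj[:, noise] == 16.0)
    assert len(res.post_spike_times) == 20  # one fire per frame


def test_determinism_bitwise(tiny_protocol, neuron):
    session = generate_session(tiny_protocol)
    devices = sample_devices(DeviceParams(), VariationModel(seed=1), 20)
    a = run_experiment(session, devices, neuron)
    b = run_experiment(session, devices, neuron)
    np.testing.assert_array_equal(a.g_trajectory, b.g_trajectory)
    np.testing.assert_array_equal(a.post_spike_times, b.post_spike_times)


def test_dt_halving_keeps_epoch_end_conductances_within_1pct(neuron):
    cfg = ProtocolConfig(n_epochs=1, p_spike=1.0, t_jitter_max=0.0, offset_max=0.0, seed=3)
    session = generate_session(cfg)
    devices = [DeviceParams()] * 20
    initial = np.full(20, 16.0)
    coarse = run_experiment(session, devices, neuron, SimConfig(dt=0.5), initial=initial)
    fine = run_experiment(session, devices, neuron, SimConfig(dt=0.25), initial=initial)
    np.testing.assert_allclose(
        coarse.g_trajectory[-1], fine.g_trajectory[-1], rtol=0.01)


def test_no_switching_without_post_spikes(neuron):
    """System-level half-select safety: with the neuron prevented from firing,
    arbitrary spike input leaves every conductance exactly unchanged."""
    quiet = dataclasses.replace(neuron, u_threshold=1e6)
    cfg = ProtocolConfig(n_epochs=2, p_spike=1.0, t_jitter_max=27.0, offset_max=216.0, seed=8)
    session = generate_session(cfg)
    devices = sample_devices(DeviceParams(), VariationModel(seed=2), 20)
    res = run_experiment(session, devices, quiet, initial=np.full(20, 16.0))
    assert len(res.post_spike_times) == 0
    assert np.all(res.g_trajectory == 16.0)


def test_membrane_recording(tiny_protocol, neuron):
    session = generate_session(tiny_protocol)
    res = run_experiment(session, [DeviceParams()] * 20, neuron,
                         SimConfig(record_membrane=True), initial=np.full(20, 16.0))
    t, u = res.membrane_trace
    assert t.size == u.size > 0
    assert np.all(np.diff(t) > 0)
    assert np.all(np.isfinite(u))
    # only the final sample before each fire may sit at/above threshold
    above = np.flatnonzero(u >= neuron.u_threshold)
    assert len(above) == len(res.post_spike_times)


def test_device_session_mismatch_rejected(tiny_protocol, neuron):
    session = generate_session(tiny_protocol)
    with pytest.raises(ConfigurationError):
        run_experiment(session, [DeviceParams()] * 5, neuron)


def test_trials_deterministic_and_unique_noise(neuron):
    cfg = ProtocolConfig(n_epochs=1, p_spike=1.0, offset_max=216.0, t_jitter_max=27.0, seed=0)
    devices = [DeviceParams()] * 20
    batch1 = run_trials(cfg, devices, neuron, n_trials=3, seed=99)
    batch2 = run_trials(cfg, devices, neuron, n_trials=3, seed=99)
    for a, b in zip(batch1, batch2):
        np.testing.assert_array_equal(a.g_trajectory, b.g_trajectory)
    # noise is regenerated per trial: trajectories differ between trials
    assert not np.array_equal(batch1[0].g_trajectory, batch1[1].g_trajectory)


def test_column_sweep_shape_and_selectivity(neuron):
    cfg = ProtocolConfig(p_spike=1.0, t_jitter_max=5.0, offset_max=27.0)
    rel = run_column_sweep(DeviceParams(), VariationModel(), cfg, neuron,
                           n_columns=3, epochs=2, seed=5)
    assert rel.shape == (3, 20)
    sync = list(cfg.synchronized_rows)
    noise = [r for r in range(20) if r not in sync]
    for c in range(3):
        assert np.median(rel[c, sync]) > np.median(rel[c, noise])


def test_column_sweep_zero_variation_no_noise_identical_columns(neuron):
    cfg = ProtocolConfig(p_spike=0.0, t_jitter_max=0.0, offset_max=0.0)
    novar = VariationModel(0, 0, 0, 0, 0, 0)
    rel = run_column_sweep(DeviceParams(), novar, cfg, neuron,
                           n_columns=3, epochs=1, seed=5)
    assert np.array_equal(rel[0], rel[1]) and np.array_equal(rel[1], rel[2])
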